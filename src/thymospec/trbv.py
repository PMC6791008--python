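"""TRBV subgroup vocabulary and CDR3 ladder conventions.

The multiplex spectratyping assay amplifies 23 TRBV subgroups (IMGT
nomenclature).  CDR3 fragment ladders are in-frame, i.e. 3-nt spaced; each
subgroup has its own absolute size offset because primers anneal at
subgroup-specific positions.
"""

from __future__ import annotations

# 23 functional TRBV subgroups resolved by the multiplex assay (IMGT names).
TRBV_SUBGROUPS: tuple[str, ...] = (
    "TRBV2",
    "TRBV3",
    "TRBV4",
    "TRBV5",
    "TRBV6",
    "TRBV7",
    "TRBV9",
    "TRBV10",
    "TRBV11",
    "TRBV12",
    "TRBV13",
    "TRBV14",
    "TRBV15",
    "TRBV16",
    "TRBV18",
    "TRBV19",
    "TRBV20",
    "TRBV24",
    "TRBV25",
    "TRBV27",
    "TRBV28",
    "TRBV29",
    "TRBV30",
)

N_TRBV = len(TRBV_SUBGROUPS)

#: in-frame CDR3 ladder spacing in nucleotides
LADDER_SPACING_NT = 3

#: default number of ladder positions per subgroup
DEFAULT_N_LENGTHS = 8


def ladder_offset(trbv: str) -> int:
    """Deterministic per-subgroup fragment-size offset (nt) for the ladder start.

    Real GeneMapper exports show subgroup-specific absolute sizes; only the
    3-nt spacing matters analytically, so any stable offset works.
    """
    idx = TRBV_SUBGROUPS.index(trbv)
    return 120 + 2 * (idx % 12)


def ladder_sizes(trbv: str, n_lengths: int = DEFAULT_N_LENGTHS) -> list[int]:
    """The in-frame fragment-size ladder (nt) for one subgroup."""
    start = ladder_offset(trbv)
    return [start + LADDER_SPACING_NT * k for k in range(n_lengths)]
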