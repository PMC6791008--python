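"""Relative telomere length by the monochrome multiplex qPCR T/S method.

Simulates a plate whose standard curves follow the telomere and
beta-globin assays (slopes -3.05 and -3.22, 1:2 reference-DNA ladder from
21 ng down to 0.16 ng), then recovers each sample's T/S ratio with
triplicate CV quality control.
"""

from thymospec import compute_ts_ratio, fit_standard_curve
from thymospec.synthetic import telomere_plate

truth = {"patient_1": 0.82, "patient_2": 1.10, "control_dna": 1.00}
plate = telomere_plate(truth, noise_sd=0.05, seed=42)

for target in ("TEL", "BG"):
    c = fit_standard_curve(plate.standards(target))
    print(f"{target}: slope {c.slope:.3f}, r2 {c.r2:.4f}, efficiency {c.efficiency_pct:.1f}%")

print()
for sid, true_ts in truth.items():
    res = compute_ts_ratio(plate, sid)
    print(f"{sid}: T/S = {res.ts_ratio:.3f} (true {true_ts:.2f}); "
          f"TEL CV {res.qc_t.cv_pct:.1f}%, BG CV {res.qc_s.cv_pct:.1f}%, "
          f"{'accepted' if res.valid else 'REJECTED'}")
# T is the ng of reference DNA matching the sample's telomere signal, S the
# ng matching its single-copy beta-globin signal; T/S ~ 1 means telomere
# content equal to the reference pool. Replicate CVs above 15% would flag
# the result invalid rather than report a number.
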