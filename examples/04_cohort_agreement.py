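"""Run the full simulated comparative study and its agreement statistics.

Simulates a small patient cohort with spinal lesions, reconstructs every
patient under six correction conditions, quantifies each lesion, and
compares every condition against the CT-based gold standard with Pearson
correlation and Bland-Altman limits of agreement, plus the per-patient
total-bone-uptake (TBU) ratio.
"""

from bonespect.study import run_study

result = run_study(seed=1, n_phantoms=3)

print(f"{result.quant.lesion_id.nunique()} lesions in "
      f"{len(result.patients)} simulated patients\n")
print("agreement with CTAC(+)SC(+)RR(+) on SUVpeak (test - reference):")
for a in result.agreements:
    print(f"  {a.test:9s} r={a.pearson_r:+.3f}  mean diff {a.mean_diff:+5.2f} "
          f" LoA [{a.loa_low:+6.2f}, {a.loa_high:+6.2f}]  "
          f"bias-slope p={a.bias_slope_p:.3f}")

ratio = result.tbu["ratio_BSAC_N"]
print(f"\nTBU(B-SAC_N)/TBU(CTAC): {ratio.mean():.2f} +/- {ratio.std():.2f} "
      f"(n={len(ratio)} patient-threshold pairs)")
# Uncorrected reconstructions (NC, AC_MINUS) read systematically low;
# the emission-segmented map correlates tightly with the CT-based gold
# standard but overestimates by the calibration-factor pairing, which is
# why its TBU ratio sits above 1.
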