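"""Exact small-sample statistics on a synthetic two-group cohort.

Generates 4 control and 4 transgenic animals with distinct CMRO2
distributions, fits the linear model per subject, and runs the exact
Mann-Whitney U test between groups plus a Friedman + Dunn model comparison
within the control group.
"""

import numpy as np

from o17mri import (
    AcquisitionProtocol,
    GroupSpec,
    KineticParams,
    NoiseSpec,
    dunn_posthoc,
    fit_linear,
    fit_three_phase,
    friedman_test,
    make_group_dataset,
    mann_whitney_exact,
)

protocol = AcquisitionProtocol(tc=3.0)
groups = [
    GroupSpec("CTR", 4, KineticParams(2.02, 0.62, 0.39), KineticParams(0.10, 0.18, 0.04)),
    GroupSpec("APP", 4, KineticParams(1.68, 0.45, 0.36), KineticParams(0.14, 0.06, 0.06)),
]
cohort = make_group_dataset(groups, protocol, NoiseSpec(sigma=0.5, seed=1))

cmro2 = {g.label: [] for g in groups}
for sub in cohort:
    cmro2[sub.group].append(fit_linear(sub.curve, alpha=0.7).cmro2)

for label, vals in cmro2.items():
    print(f"{label}: CMRO2 = {np.mean(vals):.2f} +/- {np.std(vals, ddof=1)/2:.2f} (SE), n = 4")

mw = mann_whitney_exact(cmro2["CTR"], cmro2["APP"])
print(f"Mann-Whitney U = {mw.statistic:g}, exact two-sided p = {mw.p_two_sided:.3f}")
# p = 0.029 is the smallest achievable two-sided value at n = 4 vs 4
# (complete separation: 2/70).

# model comparison within CTR: linear vs three-phase (Tc ~ 0) vs (Tc = 3 s)
matrix = []
for sub in cohort:
    if sub.group != "CTR":
        continue
    row = [
        fit_linear(sub.curve, alpha=0.7).cmro2,
        fit_three_phase(sub.curve, alpha=0.7, tc=1e-4).params.cmro2,
        fit_three_phase(sub.curve, alpha=0.7, tc=3.0).params.cmro2,
    ]
    matrix.append(row)

fr = friedman_test(matrix)
print(f"Friedman chi2 = {fr.statistic:.2f}, exact p = {fr.p_two_sided:.4f} "
      "(the choice of model shifts absolute CMRO2)")
dunn = dunn_posthoc(matrix, comparisons=[(0, 1), (0, 2)],
                    labels=["linear", "3phase_tc0", "3phase_tc3"])
for pair, res in dunn.items():
    print(f"Dunn {pair[0]} vs {pair[1]}: z = {res.statistic:.2f}, "
          f"adjusted p = {res.p_two_sided:.3f}")
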