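"""Many-to-one comparisons against a control group (Dunnett's test).

Per-experiment parameter estimates for each mutant are compared with the
wild type under a shared pooled variance, with the familywise error rate
controlled exactly via the max-|t| distribution.
"""

import numpy as np

from ctrpharm import anova_dunnett

rng = np.random.default_rng(1)
wild_type = rng.normal(9.70, 0.12, 6)
mutants = {
    "M1 (no shift)":    rng.normal(9.70, 0.12, 6),
    "M2 (small shift)": rng.normal(9.45, 0.12, 6),
    "M3 (large shift)": rng.normal(8.60, 0.12, 6),
}

res = anova_dunnett([wild_type, *mutants.values()], control_index=0)
for name, t, p, sig in zip(mutants, res.t, res.p_adjusted, res.significant):
    print(f"{name:18s} t = {t:6.2f}  adjusted p = {p:.4f}"
          + ("  *" if sig else ""))
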