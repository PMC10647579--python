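"""Why CAVI0, but not CAVI, acquires an age-by-DBP interaction.

Mechanistic-mode cohorts draw PWV from a pure aging model -- given
age, PWV is independent of DBP -- and push it through the index
formulas.  Because CAVI0 divides by DBP while CAVI uses the log-ratio
of the two pressures, the age-driven DBP decline induces a strong
negative age x DBP interaction on CAVI0 and only a weak one on CAVI.
At a study-sized n = 191 the CAVI interaction often escapes
detection, reproducing the published contrast.
"""

import numpy as np

from cavikit import GeneratorConfig, fit_interaction_model, generate_cohort

t_cavi0, t_cavi, p_cavi0, p_cavi = [], [], [], []
for rep in range(20):
    cfg = GeneratorConfig(n=191, seed=rep, mode="mechanistic")
    cohort = generate_cohort(cfg)
    for resp, tlist, plist in (("cavi0", t_cavi0, p_cavi0),
                               ("cavi", t_cavi, p_cavi)):
        fit = fit_interaction_model(cohort, resp)
        j = fit.terms.index("age_dbp")
        tlist.append(fit.tvalues[j])
        plist.append(fit.pvalues[j])

print("age x DBP interaction across 20 mechanistic cohorts (n = 191):")
print(f"  CAVI0: mean t = {np.mean(t_cavi0):+.2f}, "
      f"significant (p < 0.05) in {np.mean(np.array(p_cavi0) < 0.05):.0%}")
print(f"  CAVI : mean t = {np.mean(t_cavi):+.2f}, "
      f"significant (p < 0.05) in {np.mean(np.array(p_cavi) < 0.05):.0%}")
print("\nThe interaction is real for both (it comes from the formulas), "
      "but on CAVI it is attenuated by about half, so a 191-subject "
      "study often misses it -- the pattern the index comparison reports.")
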