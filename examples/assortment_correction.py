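"""Correct ACE components for assortative mating on education.

Spouses correlate in education; if that induces a spousal additive-genetic
correlation mu, the DZ genetic correlation exceeds the 0.5 the twin model
assumes and part of the genetic variance is misread as shared environment.
The correction A_true = a2/(1-mu), C_true = c2 - mu*A_true undoes this.
"""

from twinace import (
    max_mu_explaining_c,
    mu_from_phenotypic_assortment,
    true_from_apparent,
)

# fitted (apparent) components for men and women, and a spousal
# additive-genetic correlation of 0.13 as observed for education polygenic
# scores between spouses
for label, comps in [("men", (0.47, 0.26, 0.27)), ("women", (0.38, 0.36, 0.26))]:
    out = true_from_apparent(comps, mu=0.13)
    print(
        f"{label}: apparent a2={comps[0]:.2f}, c2={comps[1]:.2f}  ->  "
        f"corrected a2={out.a2:.2f}, c2={out.c2:.2f}"
    )

mu_star = max_mu_explaining_c((0.47, 0.26, 0.27))
print(
    f"\nmu* = {mu_star:.3f}: the spousal genetic correlation at which the"
    "\nentire male shared-environment estimate would be an assortment artifact."
)

mu_pheno = mu_from_phenotypic_assortment(r_p=0.57, h2=0.47)
print(
    f"mu = {mu_pheno:.3f} if the spousal phenotypic correlation of 0.57 were"
    "\npure phenotypic assortment at heritability 0.47 (an upper bound: under"
    "\nsocial homogamy the same 0.57 implies mu = 0)."
)
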