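"""Published regression estimates used by the worked examples.

The table below holds published regression coefficients (with standard
errors) of five bull semen-production traits — semen volume (VOL), sperm
number (NUM), concentration (CON), motility (MOT) and post-thaw motility
(aMOT) — on six inbreeding measures (F_PED, F_GRM, F_ROH2, F_ROH2_8,
F_ROH8, F_HBD) in a Japanese Black (JB) and a Holstein (HOL) bull
population.  The F_ROH2_8 and F_ROH8 coefficients come from a joint
two-class fit.  Recomputing z = beta/SE and the two-sided normal p from
these printed pairs reproduces the published significance pattern: four
traits (NUM, CON, MOT, aMOT) depressed by inbreeding in JB, one (NUM) in
HOL.
"""

from __future__ import annotations

import pandas as pd

MEASURES = ("F_PED", "F_GRM", "F_ROH2", "F_ROH2_8", "F_ROH8", "F_HBD")
TRAITS = ("VOL", "NUM", "CON", "MOT", "aMOT")

_JB = {
    "VOL": [(-0.10, 0.13), (-0.30, 0.23), (-0.17, 0.15), (-0.15, 0.22),
            (-0.10, 0.15), (-0.26, 0.16)],
    "NUM": [(-4.98, 1.39), (-9.89, 2.44), (-6.44, 1.61), (0.29, 2.33),
            (-6.06, 1.61), (-7.35, 1.72)],
    "CON": [(-0.40, 0.17), (-0.76, 0.30), (-0.51, 0.20), (0.39, 0.29),
            (-0.61, 0.20), (-0.50, 0.21)],
    "MOT": [(-0.86, 0.16), (-1.47, 0.28), (-1.03, 0.19), (0.24, 0.27),
            (-1.04, 0.18), (-1.11, 0.20)],
    "aMOT": [(-0.72, 0.23), (-1.56, 0.40), (-1.17, 0.26), (0.15, 0.38),
             (-1.13, 0.26), (-1.22, 0.28)],
}

_HOL = {
    "VOL": [(-0.16, 0.13), (-0.17, 0.15), (-0.20, 0.17), (0.03, 0.18),
            (-0.18, 0.13), (-0.24, 0.17)],
    "NUM": [(-3.38, 1.69), (-4.31, 1.95), (-4.68, 2.14), (-1.65, 2.35),
            (-3.59, 1.75), (-5.20, 2.16)],
    "CON": [(-0.20, 0.19), (-0.24, 0.22), (-0.20, 0.24), (-0.05, 0.26),
            (-0.16, 0.20), (-0.26, 0.24)],
    "MOT": [(-0.16, 1.22), (-0.43, 0.26), (-0.48, 0.28), (-0.21, 0.31),
            (-0.36, 0.23), (-0.37, 0.29)],
    "aMOT": [(-0.15, 0.26), (-0.22, 0.30), (-0.25, 0.33), (-0.02, 0.37),
             (-0.20, 0.27), (-0.14, 0.34)],
}


def published_depression_regressions() -> pd.DataFrame:
    """Long-format table: breed, trait, measure, beta, se."""
    rows = []
    for breed, tab in (("JB", _JB), ("HOL", _HOL)):
        for trait in TRAITS:
            for measure, (beta, se) in zip(MEASURES, tab[trait]):
                rows.append((breed, trait, measure, beta, se))
    return pd.DataFrame(rows, columns=["breed", "trait", "measure",
                                       "beta", "se"])


def count_affected_traits(breed: str, alpha: float = 0.05,
                          exclude=("F_ROH2_8",)) -> int:
    """Number of traits whose recomputed two-sided normal p is below
    ``alpha`` on every inbreeding measure not in ``exclude``."""
    from .depression_model import z_test

    tab = published_depression_regressions()
    tab = tab[(tab["breed"] == breed) & (~tab["measure"].isin(exclude))]
    n = 0
    for trait, grp in tab.groupby("trait"):
        ps = [z_test(b, s)[1] for b, s in zip(grp["beta"], grp["se"])]
        if all(p < alpha for p in ps):
            n += 1
    return n
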