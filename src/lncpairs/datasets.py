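"""Bundled reference data.

Ships the published 14-pair pyroptosis-derived lncRNA-pair signature for
gastric cancer (gene pairs with their LASSO Cox coefficients) so risk
scores can be computed for new samples without refitting. The published
report does not state the risk cutoff, so the model's ``cutoff`` is None;
estimate one on your own cohort with
:func:`lncpairs.signature.optimal_cutoff`.
"""

from __future__ import annotations

from typing import List, Tuple

from .pairs import OrientedPair, A_GT_B, A_LT_B
from .signature import SignatureModel

#: (gene A, gene B, coefficient) — the indicator is 1 when A > B within a sample
REFERENCE_SIGNATURE_TABLE: List[Tuple[str, str, float]] = [
    ("LINC00607", "C5orf17", 0.2793),
    ("TUSC8", "PITRM1-AS1", 0.2525),
    ("TRPM2-AS", "RP11-579D7.4", 0.2088),
    ("AC074286.1", "AC058791.1", 0.1802),
    ("MMP25-AS1", "RP11-876N24.5", 0.1766),
    ("LINC01094", "RP4-680D5.8", 0.1616),
    ("AC013275.2", "RP11-567C2.1", 0.1548),
    ("MLLT4-AS1", "RP11-21L23.2", 0.0930),
    ("LINC00607", "RP11-109E24.1", 0.0700),
    ("C10orf91", "TRPM2-AS", -0.0999),
    ("LINC01588", "RP11-73K9.2", -0.1337),
    ("RP3-522D1.1", "LINC01094", -0.1959),
    ("RP11-61A14.1", "RP11-416I2.1", -0.2067),
    ("CTD-2377D24.6", "LINC01169", -0.3038),
]


def reference_signature() -> SignatureModel:
    """The published 14-pair gastric-cancer signature as a SignatureModel.

    Pairs are stored canonically (gene_a < gene_b lexicographically); the
    orientation flag records which member the published table lists first,
    i.e. the gene whose dominance the indicator tests. Each coefficient
    applies unchanged to the indicator "first-listed gene greater than
    second-listed gene".
    """
    pairs, coefs = [], []
    for ga, gb, coef in REFERENCE_SIGNATURE_TABLE:
        a, b = sorted((ga, gb))
        orient = A_GT_B if a == ga else A_LT_B  # indicator: 1 iff expr(ga) > expr(gb)
        pairs.append(OrientedPair(a, b, orient))
        coefs.append(coef)
    return SignatureModel(
        pairs=pairs,
        coefficients=coefs,
        cutoff=None,
        training_cohort="TCGA-STAD",
        lasso_lambda=None,
        seed=None,
    )
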