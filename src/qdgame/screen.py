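"""Gene-by-gene interaction screening and qualitative classification.

For each gene the two-cell-type profile is fit with the full (game) and null
(non-game) models, tested by permutation LR, and the signed net dependent
integrals are mapped to one of eleven qualitative interaction classes
(symmetric/asymmetric synergism, directional synergism toward either type,
altruism/exploitation, symmetric/asymmetric antagonism, directional
antagonism toward either type, coexistence), then aggregated into five
regulator categories.  The same machinery applies to any two-group labeling
(e.g. mitotic vs meiotic phases) by relabeling the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import ExpressionTable, paired_profiles
from .likelihood import fit_from_theta, lr_interaction_test

logger = logging.getLogger(__name__)

#: default relative-magnitude threshold below which a dependent integral is
#: treated as neutral even when the global interaction test is significant
DEFAULT_TAU = 0.05
#: relative tolerance separating "symmetric" from "asymmetric" strengths
SYMMETRY_RTOL = 0.10

TABLE1_CLASSES = (
    "symmetric_synergism",
    "asymmetric_synergism",
    "directional_synergism_toward_k",
    "directional_synergism_toward_kprime",
    "altruism_toward_k",
    "altruism_toward_kprime",
    "symmetric_antagonism",
    "asymmetric_antagonism",
    "directional_antagonism_toward_k",
    "directional_antagonism_toward_kprime",
    "coexistence",
)

CATEGORY5 = {
    "symmetric_synergism": "synergistic",
    "asymmetric_synergism": "synergistic",
    "directional_synergism_toward_k": "directional_synergistic",
    "directional_synergism_toward_kprime": "directional_synergistic",
    "altruism_toward_k": "altruistic",
    "altruism_toward_kprime": "altruistic",
    "symmetric_antagonism": "antagonistic",
    "asymmetric_antagonism": "antagonistic",
    "directional_antagonism_toward_k": "directional_antagonistic",
    "directional_antagonism_toward_kprime": "directional_antagonistic",
    "coexistence": "none",
}


@dataclass
class InteractionCall:
    """Classified FGC-soma (type1-type2) interaction for one gene."""

    gene_id: str
    dep_12: float       # net dependent integral, type1 <- type2
    dep_21: float       # net dependent integral, type2 <- type1
    sign_12: str        # "+", "0" or "-"
    sign_21: str
    table1_class: str
    category5: str
    LR: float
    threshold: float
    significant: bool


def sign_of_dependence(net_dep: float, indep_range: float,
                       test_significant: bool, tau: float = DEFAULT_TAU) -> str:
    """Signed direction of a dependent integral, with a neutrality rule.

    Neutral ("0") when the interaction test is not significant or when the
    magnitude is below ``tau`` times the corresponding independent range.
    """
    if indep_range <= 0:
        raise ValueError("indep_range must be positive")
    if not test_significant or abs(net_dep) < tau * indep_range:
        return "0"
    return "+" if net_dep > 0 else "-"


def classify_table1(sign_12: str, sign_21: str,
                    dep_12: float = 0.0, dep_21: float = 0.0) -> str:
    """Map the two signed dependence directions to the qualitative class.

    Direction 1<-2 is "toward k" (type 1 is the recipient); symmetric vs
    asymmetric same-sign classes are split by whether |dep_12| and |dep_21|
    agree within a relative tolerance.
    """
    pair = (sign_12, sign_21)
    if pair == ("0", "0"):
        return "coexistence"
    if pair == ("+", "+") or pair == ("-", "-"):
        hi = max(abs(dep_12), abs(dep_21))
        symmetric = hi == 0 or abs(abs(dep_12) - abs(dep_21)) <= SYMMETRY_RTOL * hi
        if pair == ("+", "+"):
            return "symmetric_synergism" if symmetric else "asymmetric_synergism"
        return "symmetric_antagonism" if symmetric else "asymmetric_antagonism"
    if pair == ("+", "0"):
        return "directional_synergism_toward_k"
    if pair == ("0", "+"):
        return "directional_synergism_toward_kprime"
    if pair == ("+", "-"):
        return "altruism_toward_k"
    if pair == ("-", "+"):
        return "altruism_toward_kprime"
    if pair == ("-", "0"):
        return "directional_antagonism_toward_k"
    if pair == ("0", "-"):
        return "directional_antagonism_toward_kprime"
    raise ValueError(f"invalid sign pair {pair}")


def aggregate_category(table1_class: str) -> str:
    """Collapse the eleven qualitative classes to five regulator categories."""
    try:
        return CATEGORY5[table1_class]
    except KeyError:
        raise ValueError(f"unknown class {table1_class!r}") from None


def classify_fit(fit, test_result: dict, tau: float = DEFAULT_TAU) -> tuple:
    """(dep_12, dep_21, sign_12, sign_21, class, category) from a full fit."""
    dec = fit.decomposition
    v1, v2 = fit.spec.node_ids
    dep_12 = dec.net_dep.get((v1, v2), 0.0)
    dep_21 = dec.net_dep.get((v2, v1), 0.0)
    rng1 = max(dec.indep_range(v1), 1e-12)
    rng2 = max(dec.indep_range(v2), 1e-12)
    sig = bool(test_result["significant"])
    s12 = sign_of_dependence(dep_12, rng1, sig, tau)
    s21 = sign_of_dependence(dep_21, rng2, sig, tau)
    cls = classify_table1(s12, s21, dep_12, dep_21)
    return dep_12, dep_21, s12, s21, cls, aggregate_category(cls)


def screen_genes(table: ExpressionTable, n_perm: int = 1000, seed: int = 0, *,
                 group1: str = "type1", group2: str = "type2",
                 lop_order: int = 3, tau: float = DEFAULT_TAU,
                 level: float = 0.05, n_starts: int = 5,
                 protocol: str = "default") -> tuple[list, dict]:
    """Run the per-gene pipeline over a two-group table.

    Returns (calls, summary) where ``calls`` is a list of
    :class:`InteractionCall` (genes whose fit failed are recorded with class
    ``"unclassified"``) and ``summary`` counts genes per regulator category.
    """
    profiles = paired_profiles(table, group1, group2)
    rng = np.random.default_rng(seed)
    calls = []
    for prof in profiles:
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            test = lr_interaction_test(prof, n_perm=n_perm, seed=sub_seed,
                                       lop_order=lop_order, level=level,
                                       n_starts=n_starts, protocol=protocol)
            full = fit_from_theta(prof, test["theta_full"], mode=1,
                                  lop_order=lop_order)
            d12, d21, s12, s21, cls, cat = classify_fit(full, test, tau)
            calls.append(InteractionCall(
                gene_id=prof.gene_id, dep_12=d12, dep_21=d21,
                sign_12=s12, sign_21=s21, table1_class=cls, category5=cat,
                LR=test["LR"], threshold=test["threshold"],
                significant=bool(test["significant"])))
        except Exception as exc:
            logger.warning("gene %s unclassified: %s", prof.gene_id, exc)
            calls.append(InteractionCall(
                gene_id=prof.gene_id, dep_12=np.nan, dep_21=np.nan,
                sign_12="0", sign_21="0", table1_class="unclassified",
                category5="unclassified", LR=np.nan, threshold=np.nan,
                significant=False))
    summary = {}
    for c in calls:
        summary[c.category5] = summary.get(c.category5, 0) + 1
    return calls, summary


def calls_to_frame(calls: list):
    """Screen report as a DataFrame (one row per gene)."""
    import pandas as pd

    return pd.DataFrame([{
        "gene_id": c.gene_id, "dep_12": c.dep_12, "dep_21": c.dep_21,
        "sign_12": c.sign_12, "sign_21": c.sign_21,
        "table1_class": c.table1_class, "category5": c.category5,
        "LR": c.LR, "threshold": c.threshold, "significant": c.significant,
    } for c in calls])
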