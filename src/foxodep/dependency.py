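"""Classification of ablation-responsive proteins by foxo dependence.

Only proteins significant in the wild-type-background ablation contrast
(C vs. A) are eligible for a label.  Among these:

* **foxo_dependent** — significant in the interaction contrast
  (C - A) - (D - B); when the protein also responds significantly and in the
  same direction in the foxo-null background (D vs. B), the wild-type
  response must be the stronger of the two.  An optional looser rule labels
  same-direction, wild-type-stronger responses dependent even without
  interaction significance (off by default).
* **foxo_independent** — either the interaction confidence interval is
  *equivalent* to zero (falls inside the closed margin [-t, t]), or the
  protein shows a significant interaction driven by an *exaggerated*
  same-direction response in the foxo-null background.
* **unclassified** — everything else.

The margin ``t`` is data-derived per tissue: the minimum |log2 fold change|
among proteins significant in the interaction contrast.  Rule precedence on
(rare) conflicting evidence favours the interaction-significance branch, and
conflicts are flagged for audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DependencyThreshold

__all__ = [
    "equivalence_threshold",
    "is_equivalent",
    "classify_dependency",
]

LABELS = ("foxo_dependent", "foxo_independent", "unclassified")


def equivalence_threshold(
    interaction: pd.DataFrame, fdr: float = 0.1, tissue: str = ""
) -> DependencyThreshold:
    """Tissue margin t = min |interaction estimate| over significant proteins.

    ``interaction`` is a contrast result table with ``estimate`` and
    ``adj_p`` columns.  With no significant interaction protein the margin is
    undefined and the caller must supply ``t`` manually (config override).
    """
    sig = interaction[interaction["adj_p"] <= fdr]
    if sig.empty:
        raise ValueError(
            "no significant interaction proteins; supply the equivalence "
            "threshold t manually via configuration"
        )
    t = float(sig["estimate"].abs().min())
    return DependencyThreshold(t=t, tissue=tissue, provenance=list(sig.index))


def is_equivalent(ci_low, ci_high, t: float | DependencyThreshold):
    """True when the CI lies inside the closed interval [-t, t]."""
    margin = t.t if isinstance(t, DependencyThreshold) else float(t)
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    out = (-margin <= lo) & (hi <= margin)
    return bool(out) if out.ndim == 0 else out


def classify_dependency(
    cva: pd.DataFrame,
    dvb: pd.DataFrame,
    inter: pd.DataFrame,
    t: float | DependencyThreshold,
    allow_abrogation_without_interaction: bool = False,
    exaggeration_requires_interaction: bool = True,
) -> pd.DataFrame:
    """Label each C-vs-A-significant protein by foxo dependence.

    Parameters
    ----------
    cva, dvb, inter:
        Contrast result tables (aligned on proteins) for C vs. A, D vs. B and
        the interaction, each with ``estimate``, ``ci_low``, ``ci_high``,
        ``adj_p`` and ``significant`` columns.
    t:
        Equivalence margin for the interaction CI.
    allow_abrogation_without_interaction:
        Enable the looser dependent rule (same-direction significant response
        in both backgrounds, stronger in the wild-type background) even when
        the interaction is not significant.
    exaggeration_requires_interaction:
        When False, an exaggerated same-direction foxo-null response marks a
        protein independent regardless of interaction significance.

    Returns a table with the label, the rule that fired, the three estimates
    and significance flags, the equivalence verdict, and a conflict flag.
    """
    if not (cva.index.equals(dvb.index) and cva.index.equals(inter.index)):
        raise ValueError("contrast tables must be aligned on the same proteins")
    margin = t.t if isinstance(t, DependencyThreshold) else float(t)

    est_ca = cva["estimate"].to_numpy()
    est_db = dvb["estimate"].to_numpy()
    sig_ca = cva["significant"].to_numpy(dtype=bool)
    sig_db = dvb["significant"].to_numpy(dtype=bool)
    sig_int = inter["significant"].to_numpy(dtype=bool)
    same_sign = est_ca * est_db > 0
    equivalent = is_equivalent(
        inter["ci_low"].to_numpy(), inter["ci_high"].to_numpy(), margin
    )

    stronger_wt = np.abs(est_ca) > np.abs(est_db)
    stronger_null = np.abs(est_db) > np.abs(est_ca)

    # (i) interaction-significant dependence; the same-direction guard keeps
    # exaggerated responders out
    rule_i = sig_int & (~(same_sign & sig_db) | stronger_wt)
    # (ii) abrogation pattern without interaction significance (optional)
    rule_ii = same_sign & sig_db & stronger_wt & ~sig_int
    # (iii) interaction equivalent to zero within [-t, t]
    rule_iii = np.asarray(equivalent, dtype=bool)
    # (iv) exaggerated same-direction response in the foxo-null background
    rule_iv = same_sign & stronger_null
    if exaggeration_requires_interaction:
        rule_iv = rule_iv & sig_int

    dependent = rule_i | (rule_ii if allow_abrogation_without_interaction else False)
    independent = rule_iii | rule_iv

    labels = np.full(len(cva), "unclassified", dtype=object)
    rules = np.full(len(cva), "", dtype=object)
    conflict = np.zeros(len(cva), dtype=bool)
    for k in range(len(cva)):
        if not sig_ca[k]:
            continue
        dep = dependent[k]
        ind = independent[k]
        if dep and ind:
            conflict[k] = True
            # interaction-significance branch wins
            if rule_i[k]:
                labels[k], rules[k] = "foxo_dependent", "i"
            elif rule_iv[k] and sig_int[k]:
                labels[k], rules[k] = "foxo_independent", "iv"
            elif rule_i[k] or rule_ii[k]:
                labels[k], rules[k] = "foxo_dependent", "ii"
            else:
                labels[k], rules[k] = "foxo_independent", "iii"
        elif dep:
            labels[k] = "foxo_dependent"
            rules[k] = "i" if rule_i[k] else "ii"
        elif ind:
            labels[k] = "foxo_independent"
            rules[k] = "iii" if rule_iii[k] else "iv"

    return pd.DataFrame(
        {
            "label": labels,
            "rule": rules,
            "est_CvsA": est_ca,
            "est_DvsB": est_db,
            "est_interaction": inter["estimate"].to_numpy(),
            "sig_CvsA": sig_ca,
            "sig_DvsB": sig_db,
            "sig_interaction": sig_int,
            "equivalent": rule_iii,
            "conflict": conflict,
        },
        index=cva.index,
    )
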