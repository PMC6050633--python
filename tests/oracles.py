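"""Independent brute-force oracles for the greedy search.

These deliberately avoid the package's search internals: candidate scores
come from ``evaluate_balance`` (normalised form), fits from statsmodels
(OLS / Logit), and AUC from sklearn's ``roc_auc_score``.  Criterion values
are invariant to the normalisation constant (the slope absorbs it), so the
oracle's selections are directly comparable with the search's.
"""

import numpy as np
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from balancesel import BalanceDefinition, canonicalize, evaluate_balance

TIE_TOL = 1e-10


def oracle_value(frame, bal):
    """(criterion value, fitted balance slope) via statsmodels."""
    scores = evaluate_balance(frame.composition, bal).values
    X = sm.add_constant(np.column_stack([scores, frame.covariates]))
    if frame.response_type == "dichotomous":
        res = sm.Logit(frame.y01, X).fit(disp=0)
        return float(roc_auc_score(frame.y01, res.predict(X))), float(res.params[1])
    res = sm.OLS(frame.response, X).fit()
    return float(np.mean(res.resid**2)), float(res.params[1])


def _sign(frame):
    return 1.0 if frame.response_type == "dichotomous" else -1.0  # auc max, mse min


def oracle_first_pair(frame):
    """Exhaustive scan of all unordered pairs, deterministic tie-break on the
    sorted pair, orientation by slope sign."""
    sign = _sign(frame)
    taxa = sorted(frame.taxon_ids)
    best, best_value = None, None
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            bal = BalanceDefinition((a,), (b,))
            value, slope = oracle_value(frame, bal)
            if best is None or sign * (value - best_value) > TIE_TOL:
                best, best_value = canonicalize(bal, slope), value
    return best, best_value


def oracle_extend(frame, current):
    """Best one-taxon one-side extension of ``current`` by full enumeration."""
    sign = _sign(frame)
    used = current.taxa
    best, best_value = None, None
    for taxon in sorted(frame.taxon_ids):
        if taxon in used:
            continue
        for side in ("numerator", "denominator"):
            bal = current.add(taxon, side)
            value, _ = oracle_value(frame, bal)
            if best is None or sign * (value - best_value) > TIE_TOL:
                best, best_value = bal, value
    return best, best_value


def oracle_greedy_path(frame, max_components):
    """Full independent greedy run: exhaustive pair then argmax extensions,
    accepting only strict improvements."""
    sign = _sign(frame)
    bal, value = oracle_first_pair(frame)
    path, values = [bal], [value]
    while bal.size < min(max_components, frame.n_taxa):
        nxt, nxt_value = oracle_extend(frame, bal)
        if nxt is None or sign * (nxt_value - value) <= 0:
            break
        bal, value = nxt, nxt_value
        path.append(bal)
        values.append(value)
    return path, values
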