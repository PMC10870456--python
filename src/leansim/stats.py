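"""Group-level statistics: between-group t-tests and clinical correlations.

Per direction and parameter, the two groups are compared with an
independent two-sample t-test (Welch by default; Student's pooled-variance
variant available for strict replication).  Within the patient group,
control gains are correlated with clinical scores (UPDRS, FRT) using
Spearman's rank correlation with average-rank tie handling.  Significance
is flagged at alpha = 0.05 and 0.01; no multiple-testing correction is
applied by default (a Holm option exists).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError


def compare_groups(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("K_P", "K_FF"),
    group_col: str = "group",
    direction_col: str = "target_id",
    variant: str = "welch",
    holm: bool = False,
) -> pd.DataFrame:
    """Independent t-test per parameter per direction between two groups."""
    if variant not in ("welch", "student"):
        raise ValidationError("variant must be 'welch' or 'student'")
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two groups, got {groups}")
    g1, g2 = groups
    rows = []
    for direction, sub in table.groupby(direction_col):
        for param in parameters:
            a = sub.loc[sub[group_col] == g1, param].dropna().to_numpy()
            b = sub.loc[sub[group_col] == g2, param].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValidationError(
                    f"need >= 2 observations per group for {param} at {direction}"
                )
            t, p = sstats.ttest_ind(a, b, equal_var=(variant == "student"))
            rows.append(
                {
                    "target_id": direction,
                    "parameter": param,
                    f"mean_{g1}": a.mean(),
                    f"sd_{g1}": a.std(ddof=1),
                    f"n_{g1}": len(a),
                    f"mean_{g2}": b.mean(),
                    f"sd_{g2}": b.std(ddof=1),
                    f"n_{g2}": len(b),
                    "t": float(t),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if holm:
        out["p_adj"] = _holm(out["p"].to_numpy())
        pcol = "p_adj"
    else:
        pcol = "p"
    out["sig_05"] = out[pcol] < 0.05
    out["sig_01"] = out[pcol] < 0.01
    return out


def _holm(p):
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def correlate_clinical(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ("K_P", "K_FF"),
    scores: tuple[str, ...] = ("UPDRS", "FRT"),
    direction_col: str = "target_id",
) -> pd.DataFrame:
    """Spearman rank correlation of gains with clinical scores per direction.

    Rows with missing scores (e.g. healthy subjects, who have no clinical
    assessment) are dropped pairwise.  A constant input vector makes the
    rank correlation undefined and raises :class:`ValidationError`.
    """
    rows = []
    for direction, sub in table.groupby(direction_col):
        for param in parameters:
            for score in scores:
                pair = sub[[param, score]].dropna()
                if len(pair) < 3:
                    raise ValidationError(
                        f"need >= 3 paired observations for {param}~{score} "
                        f"at direction {direction}"
                    )
                x = pair[param].to_numpy()
                y = pair[score].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    raise ValidationError(
                        f"constant vector makes {param}~{score} correlation "
                        f"undefined at direction {direction}"
                    )
                rho, p = sstats.spearmanr(x, y)
                rows.append(
                    {
                        "target_id": direction,
                        "parameter": param,
                        "score": score,
                        "rho": float(rho),
                        "p": float(p),
                        "n": len(pair),
                        "sig_05": p < 0.05,
                        "sig_01": p < 0.01,
                    }
                )
    return pd.DataFrame(rows)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rho and p for one pair of vectors (average-rank ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: rank correlation undefined")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)
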