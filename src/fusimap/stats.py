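"""Within-subject two-way ANOVA and post-hoc comparisons.

The classical balanced repeated-measures decomposition is implemented
directly on the (subjects x factor A x factor B) cell means so that many
simulated datasets can be analysed at once (the leading axes broadcast).
No sphericity correction is applied by default; a Greenhouse-Geisser
epsilon can be requested for the univariate tests.  The implementation is
cross-checked against statsmodels' AnovaRM in the test suite.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["rm_anova_two_way", "tukey_pairwise"]

_EPS = 1e-12


def _f_p(ss: np.ndarray, df: float, ss_err: np.ndarray, df_err: float) -> Tuple[np.ndarray, np.ndarray]:
    ms = ss / df
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms / ms_err
    p = sps.f.sf(f, df, df_err)
    # exact-null degenerate case: no effect and no error variance
    degen = (ss < _EPS) & (ss_err < _EPS)
    f = np.where(degen, 0.0, f)
    p = np.where(degen, 1.0, p)
    return f, p


def rm_anova_two_way(data: np.ndarray) -> Dict[str, Dict[str, np.ndarray]]:
    """Two-way fully within-subject ANOVA on ``(..., subjects, a, b)`` data.

    Both factors are repeated measures; the design must be balanced and
    complete (no NaNs).  Returns, for effects ``"A"``, ``"B"`` and
    ``"A:B"``, dicts with ``F``, ``p``, ``df`` and ``df_err``; leading axes
    of ``data`` are carried through (vectorised replicates).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim < 3:
        raise ValueError("data must be (..., subjects, a, b)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells: repeated-measures design must be complete")
    S, A, B = y.shape[-3:]
    if S < 2 or A < 2 or B < 2:
        raise ValueError("need at least 2 subjects and 2 levels per factor")

    m = y.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = y.mean(axis=(-2, -1), keepdims=True)
    m_a = y.mean(axis=(-3, -1), keepdims=True)
    m_b = y.mean(axis=(-3, -2), keepdims=True)
    m_sa = y.mean(axis=-1, keepdims=True)
    m_sb = y.mean(axis=-2, keepdims=True)
    m_ab = y.mean(axis=-3, keepdims=True)

    ss_a = (S * B) * ((m_a - m) ** 2).sum(axis=(-3, -2, -1))
    ss_err_a = B * ((m_sa - m_s - m_a + m) ** 2).sum(axis=(-3, -2, -1))
    ss_b = (S * A) * ((m_b - m) ** 2).sum(axis=(-3, -2, -1))
    ss_err_b = A * ((m_sb - m_s - m_b + m) ** 2).sum(axis=(-3, -2, -1))
    ss_ab = S * ((m_ab - m_a - m_b + m) ** 2).sum(axis=(-3, -2, -1))
    resid = y - m_sa - m_sb - m_ab + m_s + m_a + m_b - m
    ss_err_ab = (resid**2).sum(axis=(-3, -2, -1))

    out: Dict[str, Dict[str, np.ndarray]] = {}
    for name, ss, ss_err, df, df_err in (
        ("A", ss_a, ss_err_a, A - 1, (A - 1) * (S - 1)),
        ("B", ss_b, ss_err_b, B - 1, (B - 1) * (S - 1)),
        ("A:B", ss_ab, ss_err_ab, (A - 1) * (B - 1), (A - 1) * (B - 1) * (S - 1)),
    ):
        f, p = _f_p(ss, df, ss_err, df_err)
        out[name] = {"F": f, "p": p, "df": df, "df_err": df_err, "ss": ss}
    return out


def tukey_pairwise(
    values: np.ndarray, group_names: Sequence[str]
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Tukey HSD on subject-level group means.

    ``values`` is (subjects, groups): one summary value (e.g. the
    across-window mean accuracy of a fold) per subject and group.  Returns
    the mean difference and family-wise adjusted p per group pair.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(group_names):
        raise ValueError("values must be (subjects, groups)")
    res = sps.tukey_hsd(*[values[:, j] for j in range(values.shape[1])])
    out: Dict[Tuple[str, str], Dict[str, float]] = {}
    for i in range(len(group_names)):
        for j in range(i + 1, len(group_names)):
            out[(group_names[i], group_names[j])] = {
                "mean_diff": float(values[:, i].mean() - values[:, j].mean()),
                "p": float(res.pvalue[i, j]),
            }
    return out
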