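"""Transition-state-theory bookkeeping across enzyme variants.

For an ideal transition-state analogue, the dissociation constant an enzyme
would show toward the true transition state is K_TX = (K_S/k_cat)*k_uncat,
and it should track the measured TSA dissociation constant with unit slope
in log-log space.  This module computes K_TX, the log-log correlation, and
fold-change tables relative to a reference variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scheme_core import SchemeValidationError

__all__ = [
    "VariantSummary",
    "transition_state_affinity",
    "correlate_proficiency",
    "fold_change_table",
]


@dataclass(frozen=True)
class VariantSummary:
    """Per-variant kinetic/thermodynamic summary row.

    ``k_uncat`` is a user-supplied literature constant; K_TX is always
    recomputed from (K_S, k_cat, k_uncat), never stored.
    """

    variant: str
    k_cat: float  # s^-1
    K_M: float  # M
    K_S: float  # M
    K_P: float  # M
    K_2: float  # M, TSA binding-step dissociation constant
    p_active_25C: float
    k_uncat: float  # s^-1
    k_cat_err: float = 0.0
    K_2_err: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_cat", "K_M", "K_S", "K_P", "K_2", "k_uncat"):
            if getattr(self, name) <= 0:
                raise SchemeValidationError(f"{name} must be > 0")
        if not 0 < self.p_active_25C <= 1:
            raise SchemeValidationError("p_active_25C must be in (0, 1]")

    @property
    def K_TX(self) -> float:
        return transition_state_affinity(self.K_S, self.k_cat, self.k_uncat)


def transition_state_affinity(K_S: float, k_cat: float, k_uncat: float) -> float:
    """K_TX = K_S * k_uncat / k_cat (M): ideal-TSA dissociation constant."""
    if min(K_S, k_cat, k_uncat) <= 0:
        raise SchemeValidationError("K_S, k_cat, k_uncat must all be > 0")
    return K_S * k_uncat / k_cat


def correlate_proficiency(
    summaries: Sequence[VariantSummary],
) -> dict[str, float]:
    """OLS of log10(K_TX) on log10(K_2) across variants.

    Unit slope with r ~ 1 is the transition-state-theory expectation for a
    good TSA.  Requires >= 3 variants (2 points make the regression
    degenerate).
    """
    if len(summaries) < 3:
        raise SchemeValidationError("need >= 3 variants for the log-log regression")
    x = np.log10([s.K_2 for s in summaries])
    y = np.log10([s.K_TX for s in summaries])
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return {"slope": float(slope), "intercept": float(intercept), "r": r, "n": len(summaries)}


def _ratio_with_err(a, a_err, b, b_err):
    ratio = a / b
    rel = np.sqrt((a_err / a) ** 2 + (b_err / b) ** 2)
    return ratio, abs(ratio) * rel


def fold_change_table(
    summaries: Sequence[VariantSummary], reference: str
) -> pd.DataFrame:
    """Pairwise fold changes of k_cat, k_cat/K_M, K_2, K_P vs a reference.

    Ratios are reference/variant for the dissociation constants (so "K_2
    fold improvement" > 1 means tighter binding than the reference) and
    variant/reference for rates.  Uncertainties propagate in quadrature on
    relative errors.
    """
    by_name = {s.variant: s for s in summaries}
    if reference not in by_name:
        raise SchemeValidationError(f"reference variant {reference!r} not in summaries")
    ref = by_name[reference]
    rows = []
    for s in summaries:
        kcat_fold, kcat_fold_err = _ratio_with_err(s.k_cat, s.k_cat_err, ref.k_cat, ref.k_cat_err)
        eff_fold = (s.k_cat / s.K_M) / (ref.k_cat / ref.K_M)
        k2_fold, k2_fold_err = _ratio_with_err(ref.K_2, ref.K_2_err, s.K_2, s.K_2_err)
        rows.append(
            {
                "variant": s.variant,
                "k_cat_fold": kcat_fold,
                "k_cat_fold_err": kcat_fold_err,
                "efficiency_fold": eff_fold,
                "K_2_fold": k2_fold,
                "K_2_fold_err": k2_fold_err,
                "K_P_fold": ref.K_P / s.K_P,
                "K_TX_fold": ref.K_TX / s.K_TX,
            }
        )
    return pd.DataFrame(rows).set_index("variant")
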