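"""Group-wise significance sets and correlation-loss classification.

Works on the per-metabolite, per-scope correlation tables produced by
:func:`crossfluid.robust.correlate_all` (columns: metabolite, scope, r_huber,
p_huber, r_ols, p_ols, n_obs, converged, valid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossfluid.core_io import PairedProfileTable
from crossfluid.errors import ParameterError

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ABS_R = 0.7


@dataclass
class SignificantSets:
    s_comb: set[str]
    s_pat: set[str]
    s_ctrl: set[str]
    s_shared: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.s_shared = self.s_comb & self.s_pat & self.s_ctrl

    def sizes(self) -> dict[str, int]:
        return {
            "combined": len(self.s_comb),
            "patients": len(self.s_pat),
            "controls": len(self.s_ctrl),
            "shared": len(self.s_shared),
        }


def _scope_frame(records: pd.DataFrame, scope: str) -> pd.DataFrame:
    sub = records[records["scope"] == scope]
    if sub.empty:
        raise ParameterError(f"no records for scope {scope!r}")
    return sub.set_index("metabolite")


def significant_sets(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> SignificantSets:
    """Metabolites with p_huber < alpha per scope, plus the triple intersection."""

    def sig(scope: str) -> set[str]:
        f = _scope_frame(records, scope)
        ok = f["valid"].astype(bool) & (f["p_huber"] < alpha)
        return set(f.index[ok])

    return SignificantSets(sig("combined"), sig("patients"), sig("controls"))


def classify_lost(
    records: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
) -> tuple[list[str], list[str]]:
    """Metabolites whose plasma-CSF correlation is present in exactly one group.

    lost_in_patients: significant and strong (|r| >= min_abs_r) in controls,
    not significant in patients.  lost_in_controls is the mirror image.  Each
    list is ranked by the significant scope's p-value, ascending (ties broken
    by metabolite ID).
    """
    pat = _scope_frame(records, "patients")
    ctrl = _scope_frame(records, "controls")
    common = pat.index.intersection(ctrl.index)
    pat, ctrl = pat.loc[common], ctrl.loc[common]

    valid = pat["valid"].astype(bool) & ctrl["valid"].astype(bool)
    ctrl_sig = valid & (ctrl["p_huber"] < alpha) & (ctrl["r_huber"].abs() >= min_abs_r)
    pat_sig = valid & (pat["p_huber"] < alpha) & (pat["r_huber"].abs() >= min_abs_r)

    lost_in_patients = ctrl_sig & (pat["p_huber"] >= alpha)
    lost_in_controls = pat_sig & (ctrl["p_huber"] >= alpha)

    def ranked(mask: pd.Series, by: pd.DataFrame) -> list[str]:
        chosen = by.loc[mask[mask].index]
        order = sorted(chosen.index, key=lambda m: (chosen.at[m, "p_huber"], m))
        return order

    return ranked(lost_in_patients, ctrl), ranked(lost_in_controls, pat)


def ranked_profile_export(paired: PairedProfileTable) -> pd.DataFrame:
    """Per-metabolite mean ln plasma/CSF values, sorted by increasing plasma mean.

    Ties are broken by metabolite ID so the ordering is deterministic.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pl = np.nanmean(paired.s_pl, axis=0)
        mean_csf = np.nanmean(paired.s_csf, axis=0)
    out = pd.DataFrame(
        {
            "metabolite": paired.metabolites,
            "mean_ln_plasma": mean_pl,
            "mean_ln_csf": mean_csf,
        }
    )
    out = out.sort_values(["mean_ln_plasma", "metabolite"], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class GroupComparison:
    """Bundle of the three scope tables, significance sets and lost lists."""

    records: pd.DataFrame
    sets: SignificantSets
    lost_in_patients: list[str]
    lost_in_controls: list[str]
    alpha: float
    min_abs_r: float

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "min_abs_r": self.min_abs_r,
            "set_sizes": self.sets.sizes(),
            "n_lost_in_patients": len(self.lost_in_patients),
            "n_lost_in_controls": len(self.lost_in_controls),
        }


def compare_groups(
    records: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    bh_adjust: bool = False,
) -> GroupComparison:
    """Full group comparison.  With ``bh_adjust`` the Huber p-values are
    Benjamini-Hochberg adjusted within each scope before thresholding
    (off by default: the study thresholds raw p-values)."""
    records = records.copy()
    if bh_adjust:
        from crossfluid.enrichment import bh_fdr

        for scope in records["scope"].unique():
            mask = (records["scope"] == scope) & records["valid"].astype(bool)
            records.loc[mask, "p_huber"] = bh_fdr(records.loc[mask, "p_huber"].to_numpy())
    sets = significant_sets(records, alpha)
    lost_pat, lost_ctrl = classify_lost(records, alpha, min_abs_r)
    return GroupComparison(records, sets, lost_pat, lost_ctrl, alpha, min_abs_r)
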