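"""Protein half-life integration: join frameshift candidates with measured
half-lives, assign proline-delta groups, and test the group effect.

The hypothesis under test: frameshift C-termini that *gain* proline
(P-rich group) destabilize the protein, so the P-rich subset of skipped
candidates should show shorter half-lives than the full measured proteome,
while the P-decreased and P-unchanged subsets should not.  The default test
is Welch's unequal-variance t-test on log-transformed half-lives (half-life
distributions are right-skewed); a Student-on-raw variant and a
Mann-Whitney U are available/reported for comparison.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_features import PROLINE_GROUPS, proline_group

PSI_SKIPPED_CUTOFF = 90.0
MIN_GROUP_N = 3


def join_halflife(
    candidates: pd.DataFrame,
    halflife: pd.DataFrame,
    psi_cutoff: float = PSI_SKIPPED_CUTOFF,
) -> pd.DataFrame:
    """Candidates with PSI < cutoff joined to measured half-lives.

    ``candidates`` needs columns gene_id, psi, P_fl, P_fs; ``halflife``
    needs gene_id, half_life_h.  Candidates without a measured half-life
    are dropped (counted in the result's attrs); an empty join raises with
    an id-mismatch diagnostic.
    """
    for col in ("gene_id", "psi", "P_fl", "P_fs"):
        if col not in candidates.columns:
            raise ValueError(f"candidates table missing column {col!r}")
    for col in ("gene_id", "half_life_h"):
        if col not in halflife.columns:
            raise ValueError(f"half-life table missing column {col!r}")
    skipped = candidates[candidates["psi"] < psi_cutoff]
    joined = skipped.merge(halflife, on="gene_id", how="inner")
    if joined.empty:
        example_c = sorted(candidates["gene_id"].astype(str))[:3]
        example_h = sorted(halflife["gene_id"].astype(str))[:3]
        raise ValueError(
            "empty join between candidates and half-life table; check gene id "
            f"conventions (candidates look like {example_c}, half-life like {example_h})"
        )
    joined = joined.copy()
    joined["group"] = [
        proline_group(fl, fs) for fl, fs in zip(joined["P_fl"], joined["P_fs"])
    ]
    joined.attrs["n_skipped"] = len(skipped)
    joined.attrs["n_without_halflife"] = len(skipped) - len(joined)
    return joined


def compare_groups(
    skipped: pd.DataFrame,
    all_halflives: pd.Series | np.ndarray,
    log_transform: bool = True,
    welch: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group half-life statistics and tests against all measured proteins.

    Groups with fewer than three members are reported but not tested.
    Raw two-sided p-values are reported (matching significance-star
    conventions) together with a Benjamini-Hochberg adjusted column and a
    Mann-Whitney p for comparison.
    """
    all_values = np.asarray(all_halflives, dtype=float)
    if np.any(all_values <= 0):
        raise ValueError("half-lives must be positive")
    ref = np.log(all_values) if log_transform else all_values
    rows = []
    for group in ("Skipped",) + PROLINE_GROUPS:
        if group == "Skipped":
            values = skipped["half_life_h"].to_numpy(dtype=float)
        else:
            values = skipped.loc[skipped["group"] == group, "half_life_h"].to_numpy(
                dtype=float
            )
        row = {
            "group": group,
            "n": len(values),
            "median_h": float(np.median(values)) if len(values) else np.nan,
            "mean_h": float(np.mean(values)) if len(values) else np.nan,
        }
        if len(values) >= MIN_GROUP_N:
            sample = np.log(values) if log_transform else values
            t, p = stats.ttest_ind(sample, ref, equal_var=not welch)
            u_p = stats.mannwhitneyu(values, all_values, alternative="two-sided").pvalue
            row.update(t_stat=float(t), p_value=float(p), mannwhitney_p=float(u_p))
        else:
            row.update(t_stat=np.nan, p_value=np.nan, mannwhitney_p=np.nan)
            row["note"] = "group too small; test skipped"
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = _benjamini_hochberg(out.loc[tested, "p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    out.attrs["test"] = ("welch" if welch else "student") + (
        "_log" if log_transform else "_raw"
    )
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
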