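"""Percent-spliced-in estimation from junction read counts, tissue
aggregation, alternative-splicing calls, and MAD-weighted tissue distances.

PSI for a cassette exon is estimated from three junction read classes:
``inc_up`` (upstream -> exon), ``inc_down`` (exon -> downstream) and ``exc``
(upstream -> downstream, i.e. skipping).  Because one included molecule
contributes two inclusion junctions but one excluded molecule only one
exclusion junction, inclusion reads are halved:

    psi = 100 * ((inc_up + inc_down)/2) / ((inc_up + inc_down)/2 + exc)

An event in a sample is *expressed* when its total supporting reads
(inc_up + inc_down + exc) reach a threshold (default 20); only expressed
samples enter tissue means, and an event is called alternatively spliced
when some tissue mean falls below a PSI cutoff (default 90, strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_EXPRESSION_THRESHOLD = 20
DEFAULT_PSI_CUTOFF = 90.0


@dataclass(frozen=True)
class JunctionCounts:
    event_id: str
    sample_id: str
    inc_up: int
    inc_down: int
    exc: int

    def __post_init__(self) -> None:
        for name in ("inc_up", "inc_down", "exc"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class PsiRecord:
    event_id: str
    sample_id: str
    psi: Optional[float]  # None when the denominator is zero
    supporting_reads: int
    expressed: bool


def compute_psi(
    j: JunctionCounts, expr_threshold: int = DEFAULT_EXPRESSION_THRESHOLD
) -> PsiRecord:
    """PSI and expression status for one event in one sample."""
    inc_half = (j.inc_up + j.inc_down) / 2.0
    denom = inc_half + j.exc
    psi = 100.0 * inc_half / denom if denom > 0 else None
    supporting = j.inc_up + j.inc_down + j.exc
    expressed = supporting >= expr_threshold and psi is not None
    return PsiRecord(j.event_id, j.sample_id, psi, supporting, expressed)


def compute_psi_table(
    counts: pd.DataFrame, expr_threshold: int = DEFAULT_EXPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Vectorized :func:`compute_psi` over a counts table.

    ``counts`` needs columns event_id, sample_id, inc_up, inc_down, exc.
    """
    required = {"event_id", "sample_id", "inc_up", "inc_down", "exc"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts[["inc_up", "inc_down", "exc"]] < 0).any().any():
        raise ValueError("junction counts must be non-negative")
    out = counts[["event_id", "sample_id"]].copy()
    inc_half = (counts["inc_up"] + counts["inc_down"]) / 2.0
    denom = inc_half + counts["exc"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["psi"] = np.where(denom > 0, 100.0 * inc_half / denom, np.nan)
    out["supporting_reads"] = counts[["inc_up", "inc_down", "exc"]].sum(axis=1)
    out["expressed"] = (out["supporting_reads"] >= expr_threshold) & out["psi"].notna()
    return out


def aggregate_by_tissue(
    psi_table: pd.DataFrame, sample_to_tissue: Mapping[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Events x tissues matrix of mean PSI over *expressed* samples only.

    Cells with no expressed sample are NaN.  Unknown sample ids raise.
    """
    if isinstance(sample_to_tissue, pd.DataFrame):
        sample_to_tissue = dict(
            zip(sample_to_tissue["sample_id"], sample_to_tissue["tissue"])
        )
    unknown = set(psi_table["sample_id"]) - set(sample_to_tissue)
    if unknown:
        raise ValueError(f"samples without tissue assignment: {sorted(unknown)[:5]}")
    df = psi_table.copy()
    df["tissue"] = df["sample_id"].map(sample_to_tissue)
    expressed = df[df["expressed"]]
    matrix = expressed.pivot_table(
        index="event_id", columns="tissue", values="psi", aggfunc="mean"
    )
    # keep rows for events with no expressed sample anywhere (all-NaN rows)
    all_events = pd.Index(sorted(df["event_id"].unique()), name="event_id")
    all_tissues = pd.Index(sorted(set(sample_to_tissue.values())), name="tissue")
    return matrix.reindex(index=all_events, columns=all_tissues)


def call_alternative(
    matrix: pd.DataFrame, psi_cutoff: float = DEFAULT_PSI_CUTOFF
) -> pd.DataFrame:
    """Per-event call: alternatively spliced iff some tissue PSI < cutoff
    (strict).  Events with an all-empty row are flagged not testable."""
    testable = matrix.notna().any(axis=1)
    alternative = (matrix < psi_cutoff).any(axis=1) & testable
    return pd.DataFrame({"testable": testable, "alternative": alternative})


def psi_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """PSI_MIN / PSI_MEDIAN / PSI_MEAN / PSI_MAX per event over non-empty cells."""
    return pd.DataFrame(
        {
            "PSI_MIN": matrix.min(axis=1),
            "PSI_MEDIAN": matrix.median(axis=1),
            "PSI_MEAN": matrix.mean(axis=1),
            "PSI_MAX": matrix.max(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# MAD-weighted tissue distance
# ---------------------------------------------------------------------------

def _mad(values: np.ndarray) -> np.ndarray:
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with non-negative weights."""
    w = np.asarray(w, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    wn = w / w.sum()
    mx, my = wn @ x, wn @ y
    cov = wn @ ((x - mx) * (y - my))
    vx, vy = wn @ ((x - mx) ** 2), wn @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def tissue_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tissues x tissues distance: 1 minus the weighted Pearson correlation
    of PSI profiles, each event weighted by the MAD of its PSI row (more
    variable exons weigh more).  Events with any empty cell are dropped."""
    complete = matrix.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no events with complete PSI rows")
    values = complete.to_numpy(dtype=float)
    w = _mad(values)
    if w.sum() <= 0:
        raise ValueError("all event weights (MADs) are zero")
    tissues = list(complete.columns)
    n = len(tissues)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = weighted_pearson(values[:, i], values[:, j], w)
            d[i, j] = d[j, i] = 1.0 - r
    return pd.DataFrame(d, index=tissues, columns=tissues)


def tsne_embed(distance: pd.DataFrame, seed: int = 0, perplexity: Optional[float] = None):
    """2-D t-SNE embedding of a precomputed distance matrix (plotting
    convenience; stochastic, hence the fixed seed)."""
    from sklearn.manifold import TSNE

    n = distance.shape[0]
    if perplexity is None:
        perplexity = max(1.0, min(30.0, (n - 1) / 3.0))
    emb = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    ).fit_transform(distance.to_numpy())
    return pd.DataFrame(emb, index=distance.index, columns=["tsne1", "tsne2"])


# ---------------------------------------------------------------------------
# target/background sets for RBP motif discovery
# ---------------------------------------------------------------------------

def select_motif_sets(
    matrix: pd.DataFrame,
    high: float = 90.0,
    low: float = 20.0,
    min_delta: float = 50.0,
) -> tuple[list[str], list[str]]:
    """Split differentiation-stage PSI rows into motif-search sets.

    Only events expressed at every stage (complete rows) are considered.
    Background: constitutively included (PSI > high everywhere) or excluded
    (PSI < low everywhere).  Target: max - min PSI > min_delta between any
    two stages.  The two sets are disjoint by construction.
    """
    complete = matrix.dropna(axis=0, how="any")
    is_bg = (complete > high).all(axis=1) | (complete < low).all(axis=1)
    delta = complete.max(axis=1) - complete.min(axis=1)
    is_target = (delta > min_delta) & ~is_bg
    return sorted(complete.index[is_target]), sorted(complete.index[is_bg])


def exon_with_flanks(candidate, genome, flank: int = 50) -> str:
    """Skipped-exon sequence with ``flank`` bp of flanking intron on each
    side, transcript orientation — input material for motif discovery."""
    from Bio.Seq import reverse_complement

    e = candidate.skip_event
    chrom = genome[e.chrom]
    start = max(0, e.exon_start - flank)
    end = min(len(chrom), e.exon_end + flank)
    raw = chrom.fetch(start, end)
    return raw if e.strand == "+" else reverse_complement(raw)


def write_motif_fastas(
    target_ids: Sequence[str],
    background_ids: Sequence[str],
    candidates_by_event: Mapping[str, object],
    genome,
    target_path,
    background_path,
    flank: int = 50,
) -> None:
    for ids, path in ((target_ids, target_path), (background_ids, background_path)):
        with open(path, "w") as fh:
            for eid in ids:
                cand = candidates_by_event.get(eid)
                if cand is None:
                    continue
                fh.write(f">{eid}\n{exon_with_flanks(cand, genome, flank)}\n")
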