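"""Differential flux analysis between day and night phases.

The chain: ACHR flux sampling over the diel model's polytope → per-pair
two-sample rank test (day copy's sampled fluxes vs night copy's) with
Benjamini–Hochberg FDR → hypergeometric pathway enrichment over the
significant pairs → PCA of the significant reaction rows with a Euclidean
overlap criterion in (PC1, PC2).

The rank test is Mann–Whitney U (two-sided) by default — distribution-free
and robust to non-Gaussian sampled flux marginals; Kolmogorov–Smirnov is
available via ``method="ks"``. The whole chain is deterministic given
(model, n, seed, alpha, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from cobra.sampling import ACHRSampler

from .errors import DFAError
from .interop import to_cobra
from .model import MetabolicModel
from .pipeline import PhaseMap

DEFAULT_ALPHA = 0.05
DEFAULT_THINNING = 100
DEFAULT_DISTANCE_THRESHOLD = 1.0


@dataclass
class SampleMatrix:
    """Reactions × samples flux table from the ACHR walk."""

    reaction_ids: List[str]
    samples: np.ndarray  # shape (n_reactions, n_samples)
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != len(self.reaction_ids):
            raise DFAError(
                f"sample matrix has {self.samples.shape[0]} rows but "
                f"{len(self.reaction_ids)} reaction ids"
            )
        self._index = {rid: i for i, rid in enumerate(self.reaction_ids)}

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def row(self, rid: str) -> np.ndarray:
        try:
            return self.samples[self._index[rid]]
        except KeyError:
            raise DFAError(f"reaction {rid!r} not in sample matrix")

    def __contains__(self, rid: str) -> bool:
        return rid in self._index


def sample_fluxes(
    model: MetabolicModel,
    n: int,
    seed: int,
    thinning: int = DEFAULT_THINNING,
) -> SampleMatrix:
    """Draw ``n`` post-thinning ACHR samples from the flux polytope.

    Artificial-centering hit-and-run: directions are drawn through the
    running center of previous samples, which mixes well on the elongated
    polytopes of GEMs. All model bounds are finite here (the pipeline never
    widens beyond the configured default bound), so the polytope is
    bounded. Reproducible given ``seed``.
    """
    if n < 2:
        raise DFAError(f"need at least 2 samples, got {n}")
    cm = to_cobra(model)
    if np.isnan(cm.slim_optimize(error_value=float("nan"))):
        raise DFAError("model is infeasible; cannot sample its flux polytope")
    sampler = ACHRSampler(cm, thinning=thinning, seed=seed)
    frame = sampler.sample(n)  # samples × reactions
    reaction_ids = model.reaction_ids()
    return SampleMatrix(
        reaction_ids=reaction_ids,
        samples=frame[reaction_ids].to_numpy().T,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    reaction_id: str  # original (pre-duplication) id
    pair: Tuple[str, str]  # (day copy, night copy)
    statistic: float
    p_value: float
    q_value: float = 1.0
    significant: bool = False


def _rank_test(day: np.ndarray, night: np.ndarray, method: str) -> Tuple[float, float]:
    if np.ptp(day) == 0 and np.ptp(night) == 0 and day[0] == night[0]:
        # all-tied pair: no evidence of a shift by convention
        return len(day) * len(night) / 2.0, 1.0
    if method == "mannwhitney":
        res = stats.mannwhitneyu(day, night, alternative="two-sided")
    elif method == "ks":
        res = stats.ks_2samp(day, night)
    else:
        raise DFAError(f"unknown test method {method!r}")
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return float(res.statistic), p


def differential_reactions(
    samples: SampleMatrix,
    phase_map: PhaseMap,
    alpha: float = DEFAULT_ALPHA,
    method: str = "mannwhitney",
) -> List[DifferentialResult]:
    """Rank-test every (day, night) reaction pair; BH-correct across pairs."""
    pairs = phase_map.reaction_pairs()
    if not pairs:
        raise DFAError("phase map contains no reaction pairs")
    missing = [
        rid for _, day_id, night_id in pairs for rid in (day_id, night_id)
        if rid not in samples
    ]
    if missing:
        raise DFAError(
            "sample matrix lacks phase copies: " + ", ".join(sorted(set(missing)))
        )

    results: List[DifferentialResult] = []
    pvals: List[float] = []
    for orig, day_id, night_id in pairs:
        stat, p = _rank_test(samples.row(day_id), samples.row(night_id), method)
        results.append(
            DifferentialResult(
                reaction_id=orig, pair=(day_id, night_id), statistic=stat, p_value=p
            )
        )
        pvals.append(p)

    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for res, q, sig in zip(results, qvals, reject):
        res.q_value = float(q)
        res.significant = bool(sig)
    return results


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # significant pairs in pathway
    K: int  # pathway size in universe
    n: int  # total significant pairs in universe
    N: int  # universe size
    p_value: float


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pathway_enrichment(
    diff: List[DifferentialResult],
    model: MetabolicModel,
    phase_map: Optional[PhaseMap] = None,
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of significant pairs per pathway.

    The universe is the set of pathway-labelled reaction *pairs* (a pair's
    pathway is read from its day copy, which inherited the original's
    label); unlabelled reactions are excluded. Results sorted by p-value.
    """
    pathway_of: Dict[str, str] = {}
    labelled = {r.id: r.pathway for r in model.reactions if r.pathway}
    for res in diff:
        day_id = res.pair[0]
        label = labelled.get(day_id) or labelled.get(res.reaction_id)
        if label:
            pathway_of[res.reaction_id] = label
    if not pathway_of:
        raise DFAError(
            "no reaction in the tested pairs carries a pathway label; "
            "enrichment is undefined"
        )

    universe = [r for r in diff if r.reaction_id in pathway_of]
    N = len(universe)
    n = sum(1 for r in universe if r.significant)
    by_pathway: Dict[str, List[DifferentialResult]] = {}
    for r in universe:
        by_pathway.setdefault(pathway_of[r.reaction_id], []).append(r)

    results = []
    for pathway, members in by_pathway.items():
        K = len(members)
        k = sum(1 for r in members if r.significant)
        results.append(
            EnrichmentResult(
                pathway=pathway, k=k, K=K, n=n, N=N,
                p_value=hypergeometric_upper_tail(N, K, n, k),
            )
        )
    results.sort(key=lambda e: (e.p_value, e.pathway))
    return results


# ---------------------------------------------------------------------------
# PCA overlap
# ---------------------------------------------------------------------------

@dataclass
class PCAOverlapResult:
    explained_variance: Tuple[float, float]
    overlapping_pairs: List[Tuple[str, str]]
    overlap_fraction: float
    distances: Dict[str, float] = field(default_factory=dict)
    coordinates: Dict[str, np.ndarray] = field(default_factory=dict)


def pca_overlap(
    samples: SampleMatrix,
    diff: List[DifferentialResult],
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> PCAOverlapResult:
    """Project significant day/night reaction rows onto (PC1, PC2).

    Each significant pair contributes two points — the day copy's sampled
    flux row and the night copy's. A pair "overlaps" when the Euclidean
    distance between its two points in the first two principal components
    is at most ``distance_threshold``. No variance scaling is applied, so
    flux magnitude differences survive the projection.
    """
    significant = [r for r in diff if r.significant]
    if len(significant) < 3:
        raise DFAError(
            f"PCA overlap needs at least 3 significant pairs, got {len(significant)}"
        )

    rows = []
    for res in significant:
        rows.append(samples.row(res.pair[0]))
        rows.append(samples.row(res.pair[1]))
    X = np.vstack(rows)

    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_

    overlapping: List[Tuple[str, str]] = []
    distances: Dict[str, float] = {}
    coordinates: Dict[str, np.ndarray] = {}
    for i, res in enumerate(significant):
        day_pt, night_pt = coords[2 * i], coords[2 * i + 1]
        d = float(np.linalg.norm(day_pt - night_pt))
        distances[res.reaction_id] = d
        coordinates[res.pair[0]] = day_pt
        coordinates[res.pair[1]] = night_pt
        if d <= distance_threshold:
            overlapping.append(res.pair)

    return PCAOverlapResult(
        explained_variance=(float(evr[0]), float(evr[1])),
        overlapping_pairs=overlapping,
        overlap_fraction=len(overlapping) / len(significant),
        distances=distances,
        coordinates=coordinates,
    )
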