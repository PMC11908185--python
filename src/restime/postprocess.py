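"""Chain post-processing: from raw Gibbs samples to labeled kinetic clusters.

The mixture posterior is invariant under permutation of component
indices, so component k of one Gibbs sample and component k of the next
need not describe the same physical process ("label switching").  The
procedure here restores interpretable labels:

1. per sample, drop components whose weight implies fewer than ~10
   expected events (pi_k < numerator/Omega);
2. take K' as the modal number of survivors across samples;
3. fit a K'-component Gaussian mixture in (log lambda, log pi) space on
   the samples with exactly K' survivors, then assign every surviving
   component of every sample to a cluster (a many-to-one map);
4. flag clusters to which no event is ever confidently attributed
   (max_n p_{n,k'} below a threshold) as noise;
5. report per-cluster MAP rates/residence times with 95% percentile
   intervals.

Clusters are re-indexed by decreasing MAP rate (fastest = 0) so outputs
are deterministic and comparable across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .gibbs import GibbsChain

__all__ = [
    "MapEstimate",
    "KineticCluster",
    "ClusterModel",
    "MembershipMatrix",
    "ResidueFingerprint",
    "filter_weights",
    "mode_component_count",
    "correct_labels",
    "membership_matrix",
    "remove_noise",
    "map_estimate",
    "tau_posterior",
    "fingerprint",
    "cluster_report",
]

DEFAULT_WEIGHT_NUMERATOR = 10.0
DEFAULT_NOISE_THRESHOLD = 0.4
MIN_MAP_SAMPLES = 20


@dataclass(frozen=True)
class MapEstimate:
    """Posterior mode of a sampled scalar with a 95% percentile interval."""

    value: float
    ci: tuple
    multimodal: bool = False


@dataclass
class KineticCluster:
    """One kinetic component after label-switching correction."""

    index: int
    rates: np.ndarray    # lambda samples, 1/ns
    weights: np.ndarray  # pi samples
    map_lambda: MapEstimate
    map_tau: MapEstimate
    map_weight: MapEstimate
    noise: bool = False

    @property
    def n_samples(self) -> int:
        return self.rates.size


@dataclass
class ClusterModel:
    """K' clusters plus the (sample, component) -> cluster assignment map.

    ``assignment`` has shape (w, K); entry -1 marks a weight-filtered
    component, otherwise it holds the cluster index of that sampled
    component (the many-to-one map C_{K,K'}).
    """

    k_prime: int
    clusters: list
    assignment: np.ndarray
    omega: int

    def __post_init__(self) -> None:
        if not 1 <= self.k_prime:
            raise ValueError("k_prime must be >= 1")

    @property
    def noise_flags(self) -> np.ndarray:
        return np.array([c.noise for c in self.clusters])

    @property
    def non_noise(self) -> list:
        return [c for c in self.clusters if not c.noise]

    @property
    def tau(self) -> float:
        """Residence time of the slowest non-noise cluster (ns)."""
        keep = self.non_noise
        if not keep:
            raise ValueError("all clusters are flagged as noise")
        return max(c.map_tau.value for c in keep)

    @property
    def slowest(self) -> KineticCluster:
        keep = self.non_noise
        if not keep:
            raise ValueError("all clusters are flagged as noise")
        return max(keep, key=lambda c: c.map_tau.value)


@dataclass(frozen=True)
class MembershipMatrix:
    """Per-event posterior cluster-membership probabilities p_{n,k'}.

    Rows may sum to less than 1: samples in which the event's component
    was weight-filtered contribute no cluster mass.  The per-row deficit
    is reported as ``unassigned`` rather than renormalized away.
    """

    probabilities: np.ndarray  # (Omega, K')
    unassigned: np.ndarray     # (Omega,)


@dataclass(frozen=True)
class ResidueFingerprint:
    residue_id: object
    tau: float
    ci: tuple
    n_clusters: int
    omega: int
    flagged: bool = False


def filter_weights(state, omega: int,
                   numerator: float = DEFAULT_WEIGHT_NUMERATOR) -> np.ndarray:
    """Indices of components supported by the data in one sample.

    A component survives if its weight implies at least ``numerator``
    (default 10) expected events: pi_k >= numerator / Omega.  The
    boundary is inclusive.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    w = np.asarray(getattr(state, "weights", state), float)
    return np.flatnonzero(w >= numerator / omega)


def _survivor_mask(chain: GibbsChain,
                   numerator: float = DEFAULT_WEIGHT_NUMERATOR) -> np.ndarray:
    return chain.weights >= numerator / chain.omega


def mode_component_count(chain: GibbsChain, omega: int | None = None,
                         numerator: float = DEFAULT_WEIGHT_NUMERATOR) -> int:
    """Modal number of weight-filter survivors across kept samples.

    Ties are broken toward the larger count: losing a rare slow
    component is the costlier error.
    """
    omega = chain.omega if omega is None else omega
    counts = (chain.weights >= numerator / omega).sum(axis=1)
    bc = np.bincount(counts)
    k_prime = int(np.flatnonzero(bc == bc.max()).max())
    if k_prime < 1:
        raise ValueError("no sample has any surviving component; "
                         "inspect the chain and weight filter")
    return k_prime


def _summarize(values: np.ndarray, taus: bool = False) -> MapEstimate:
    """MAP/CI summary tolerant of very small clusters (falls back to median)."""
    if values.size == 0:
        return MapEstimate(value=np.nan, ci=(np.nan, np.nan))
    if values.size >= MIN_MAP_SAMPLES:
        return tau_posterior(values) if taus else map_estimate(values)
    v = float(np.median(1.0 / values)) if taus else float(np.median(values))
    lo, hi = np.percentile(values, [2.5, 97.5])
    ci = (1.0 / hi, 1.0 / lo) if taus else (lo, hi)
    return MapEstimate(value=v, ci=(float(ci[0]), float(ci[1])))


def correct_labels(chain: GibbsChain, k_prime: int | None = None,
                   numerator: float = DEFAULT_WEIGHT_NUMERATOR,
                   seed: int | None = None, n_init: int = 10) -> ClusterModel:
    """Cluster surviving sampled components in (log lambda, log pi) space.

    Samples with exactly K' survivors form the training set for a
    K'-component full-covariance Gaussian mixture; the fitted mixture
    then partitions the surviving components of *all* samples.  Training
    points are sorted before fitting so the result does not depend on
    component order within samples.
    """
    mask = _survivor_mask(chain, numerator)
    if k_prime is None:
        k_prime = mode_component_count(chain, numerator=numerator)
    counts = mask.sum(axis=1)
    train = counts == k_prime
    if not train.any():
        raise ValueError(
            f"no sample has exactly K'={k_prime} surviving components; "
            "inspect the chain and the weight filter")
    if seed is None:
        seed = chain.config.seed

    i_idx, k_idx = np.nonzero(mask)
    X = np.column_stack([np.log(chain.rates[mask]), np.log(chain.weights[mask])])
    if k_prime == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        X_train = X[train[i_idx]]
        X_train = X_train[np.lexsort((X_train[:, 1], X_train[:, 0]))]
        gmm = GaussianMixture(n_components=k_prime, covariance_type="full",
                              n_init=n_init, random_state=seed).fit(X_train)
        labels = gmm.predict(X)

    # order clusters by decreasing rate summary: fastest = 0
    lam_flat = chain.rates[mask]
    pi_flat = chain.weights[mask]
    summaries = []
    for c in range(k_prime):
        sel = labels == c
        summaries.append(_summarize(lam_flat[sel]) if sel.any()
                         else MapEstimate(np.nan, (np.nan, np.nan)))
    order = np.argsort([-s.value for s in summaries], kind="stable")
    relabel = np.empty(k_prime, dtype=int)
    relabel[order] = np.arange(k_prime)
    labels = relabel[labels]

    assignment = np.full(chain.weights.shape, -1, dtype=np.int16)
    assignment[i_idx, k_idx] = labels

    clusters = []
    for c in range(k_prime):
        sel = labels == c
        lam_c = lam_flat[sel]
        pi_c = pi_flat[sel]
        clusters.append(
            KineticCluster(
                index=c, rates=lam_c, weights=pi_c,
                map_lambda=_summarize(lam_c),
                map_tau=_summarize(lam_c, taus=True),
                map_weight=_summarize(pi_c),
            )
        )
    return ClusterModel(k_prime=k_prime, clusters=clusters,
                        assignment=assignment, omega=chain.omega)


def membership_matrix(chain: GibbsChain, model: ClusterModel) -> MembershipMatrix:
    """p_{n,k'}: fraction of kept samples mapping event n to cluster k'."""
    w = chain.w
    mapped = model.assignment[np.arange(w)[:, None], chain.indicators]
    P = np.empty((chain.omega, model.k_prime))
    for c in range(model.k_prime):
        P[:, c] = (mapped == c).mean(axis=0)
    return MembershipMatrix(probabilities=P, unassigned=1.0 - P.sum(axis=1))


def remove_noise(model: ClusterModel, memberships: MembershipMatrix,
                 threshold: float = DEFAULT_NOISE_THRESHOLD) -> ClusterModel:
    """Flag clusters no event is ever confidently attributed to.

    Cluster k' is noise iff max_n p_{n,k'} < threshold (default 0.4):
    not a single residence time would be assigned to it with at least
    that probability.
    """
    col_max = memberships.probabilities.max(axis=0)
    noise = col_max < threshold
    if noise.all():
        raise ValueError("every cluster was flagged as noise; no signal "
                         "survives the membership threshold")
    clusters = [dataclasses.replace(c, noise=bool(noise[c.index]))
                for c in model.clusters]
    return dataclasses.replace(model, clusters=clusters)


def _histogram(x: np.ndarray, max_bins: int = 1000):
    # Freedman-Diaconis bin width, falling back to 50 bins when the IQR
    # degenerates and capping the count for near-constant samples
    q75, q25 = np.percentile(x, [75, 25])
    width = 2.0 * (q75 - q25) / x.size ** (1.0 / 3.0)
    span = x.max() - x.min()
    if width > 0 and np.isfinite(span / width):
        nbins = int(np.clip(np.ceil(span / width), 2, max_bins))
    else:
        nbins = 50
    # never ask for bins narrower than the float resolution of the data
    scale = max(abs(x.min()), abs(x.max()))
    nbins = min(nbins, max(2, int(span / (4 * np.spacing(scale)))))
    return np.histogram(x, bins=nbins)


def _is_multimodal(counts: np.ndarray) -> bool:
    # multimodal if >= 2 runs of bins reaching half the peak height,
    # separated by a valley below half height
    high = counts >= 0.5 * counts.max()
    runs = np.diff(np.concatenate(([0], high.astype(np.int8), [0])))
    return int((runs == 1).sum()) >= 2


def map_estimate(samples, min_samples: int = MIN_MAP_SAMPLES) -> MapEstimate:
    """Posterior mode via histogram (Freedman-Diaconis bins) plus 95% CI.

    The mode is the midpoint of the highest-count bin; count ties go to
    the lower-valued bin and trigger no error.  The CI is the 2.5/97.5
    percentile interval of the samples.
    """
    x = np.asarray(samples, float).ravel()
    if x.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples for a MAP estimate; "
            "run a longer chain")
    lo, hi = np.percentile(x, [2.5, 97.5])
    scale = max(abs(float(x.min())), abs(float(x.max())))
    if x.max() - x.min() <= 16 * np.spacing(scale):
        # (numerically) constant samples: degenerate estimate
        return MapEstimate(value=float(np.median(x)),
                           ci=(float(lo), float(hi)))
    counts, edges = _histogram(x)
    b = int(np.argmax(counts))
    return MapEstimate(value=float(0.5 * (edges[b] + edges[b + 1])),
                       ci=(float(lo), float(hi)),
                       multimodal=_is_multimodal(counts))


def tau_posterior(rate_samples) -> MapEstimate:
    """MAP residence time from rate samples via tau = 1/lambda.

    The histogram is taken over the reciprocals, so in general
    MAP(tau) != 1/MAP(lambda) (the transform carries a Jacobian); both
    are reported by the cluster model.  The CI endpoints are the
    reciprocals of the swapped rate percentiles, exact under the
    monotone decreasing transform.
    """
    lam = np.asarray(rate_samples, float).ravel()
    if np.any(lam <= 0):
        raise ValueError("rates must be positive")
    est = map_estimate(1.0 / lam)
    lo, hi = np.percentile(lam, [2.5, 97.5])
    return MapEstimate(value=est.value, ci=(float(1.0 / hi), float(1.0 / lo)),
                       multimodal=est.multimodal)


def fingerprint(models: dict) -> pd.DataFrame:
    """Per-residue slowest-cluster residence times as a sortable table.

    ``models`` maps residue id -> ClusterModel (noise already flagged).
    Residues whose tau is at least four times the mean tau over the
    table are flagged as long-residence outliers.
    """
    if not models:
        raise ValueError("need at least one residue")
    rows = []
    for rid, model in models.items():
        slow = model.slowest
        rows.append({
            "residue_id": rid,
            "tau_ns": slow.map_tau.value,
            "ci_lo": slow.map_tau.ci[0],
            "ci_hi": slow.map_tau.ci[1],
            "n_clusters": len(model.non_noise),
            "omega": model.omega,
        })
    df = pd.DataFrame(rows)
    df["flagged"] = df["tau_ns"] >= 4.0 * df["tau_ns"].mean()
    return df


def cluster_report(model: ClusterModel) -> dict:
    """JSON-serializable per-cluster summary (MAP/CI for lambda and tau)."""
    return {
        "k_prime": model.k_prime,
        "omega": model.omega,
        "clusters": [
            {
                "index": c.index,
                "noise": bool(c.noise),
                "n_samples": int(c.n_samples),
                "map_lambda_per_ns": c.map_lambda.value,
                "ci_lambda_per_ns": list(c.map_lambda.ci),
                "map_tau_ns": c.map_tau.value,
                "ci_tau_ns": list(c.map_tau.ci),
                "map_weight": c.map_weight.value,
                "ci_weight": list(c.map_weight.ci),
                "multimodal": bool(c.map_lambda.multimodal or c.map_tau.multimodal),
            }
            for c in model.clusters
        ],
    }
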