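"""Functional-network inference from phase locking — comparator biomarker 2.

Edges of the functional network connect channel pairs whose low-alpha-band
phases lock more strongly than expected under a surrogate null, at a phase
lag away from 0 and pi.  The phase-locking factor (PLF) between channels a
and b is

    PLF = | mean_t exp( i (phi_a(t) - phi_b(t)) ) |,

1 for perfect locking and about (sqrt(pi)/2)/sqrt(T) for T independent
phases.  The lag is the circular mean of the phase difference; lags at 0 or
pi are excluded from the graph because a single cortical source seen by two
electrodes (volume conduction) produces exactly such zero-lag locking.

Significance comes from circular time-shift surrogates: shifting one
channel's phase series by at least one second preserves its marginal
dynamics while destroying its temporal relation to the other channel, so
the surrogate PLF distribution is the pairwise null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .segment import EEGSegment


class PhaseError(ValueError):
    pass


def instantaneous_phase(seg: EEGSegment) -> np.ndarray:
    """Analytic-signal (Hilbert) phase of every channel, in radians.

    Meaningful only for narrowband input; a broadband or raw segment raises
    a warning because its instantaneous phase is ill-defined.  Constant
    channels have no phase and raise.
    """
    if seg.band not in ("alpha", "low_alpha"):
        warnings.warn(
            f"instantaneous phase of a {seg.band!r} segment is ill-defined; "
            "band-filter first",
            stacklevel=2,
        )
    flat = np.ptp(seg.data, axis=1) == 0
    if flat.any():
        ch = int(np.argmax(flat))
        raise PhaseError(
            f"channel {seg.channel_labels[ch]} is constant: phase undefined"
        )
    return np.angle(hilbert(seg.data, axis=1))


def plf_pair(phi_a: np.ndarray, phi_b: np.ndarray) -> tuple[float, float]:
    """PLF and mean phase lag between two phase series.

    Returns ``(plf, lag)`` with ``plf`` in [0, 1] and ``lag`` the circular
    mean of ``phi_a - phi_b`` in (-pi, pi].  Series must have equal length
    of at least 100 samples (trim edges before calling).
    """
    phi_a = np.asarray(phi_a, float)
    phi_b = np.asarray(phi_b, float)
    if phi_a.shape != phi_b.shape:
        raise PhaseError(f"length mismatch: {phi_a.shape} vs {phi_b.shape}")
    if phi_a.size < 100:
        raise PhaseError(f"need >= 100 samples, got {phi_a.size}")
    r = np.exp(1j * (phi_a - phi_b)).mean()
    return float(abs(r)), float(np.angle(r))


def _trim_slice(n_samples: int, edge_fraction: float) -> slice:
    k = int(round(n_samples * edge_fraction))
    return slice(k, n_samples - k if k else n_samples)


def plf_matrix(phases: np.ndarray, edge_fraction: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs PLF and lag matrices from a channels x samples phase array.

    A fraction of samples at each end is discarded against filter and
    Hilbert edge effects.  The PLF matrix is symmetric with unit diagonal;
    the lag matrix is exactly antisymmetric.
    """
    sl = _trim_slice(phases.shape[1], edge_fraction)
    E = np.exp(1j * phases[:, sl])
    R = E @ E.conj().T / E.shape[1]
    return np.abs(R), np.angle(R)


def surrogate_threshold(
    seg_or_phases,
    n_surrogates: int = 99,
    alpha_level: float = 0.05,
    min_shift_s: float = 1.0,
    sample_rate: float | None = None,
    edge_fraction: float = 0.05,
    seed: int = 0,
    per_pair: bool = True,
) -> np.ndarray:
    """Per-pair PLF significance thresholds from circular-shift surrogates.

    For each surrogate realization one channel of a pair is circularly
    shifted by a random offset of at least ``min_shift_s`` seconds; the
    threshold for a pair is the order statistic of its surrogate PLFs such
    that a null pair exceeds it with probability ``alpha_level`` exactly
    (requiring ``alpha_level * (n_surrogates + 1) >= 1``).  With
    ``per_pair=False`` a single global threshold (the same order statistic
    of the pooled surrogate PLFs) is broadcast to all pairs.
    """
    if isinstance(seg_or_phases, EEGSegment):
        phases = instantaneous_phase(seg_or_phases)
        sample_rate = seg_or_phases.sample_rate
    else:
        phases = np.asarray(seg_or_phases, float)
        if sample_rate is None:
            raise PhaseError("sample_rate required when passing a raw phase array")
    k_exceed = int(np.floor(alpha_level * (n_surrogates + 1)))
    if k_exceed < 1:
        raise PhaseError(
            f"{n_surrogates} surrogates cannot resolve alpha_level={alpha_level}; "
            f"need at least {int(np.ceil(1 / alpha_level)) - 1}"
        )
    n, T = phases.shape
    min_shift = int(round(min_shift_s * sample_rate))
    if not 0 < min_shift < T - min_shift:
        raise PhaseError("segment too short for the requested minimum surrogate shift")
    rng = np.random.default_rng(seed)
    sl = _trim_slice(T, edge_fraction)
    E0 = np.exp(1j * phases[:, sl])
    Tt = E0.shape[1]
    surr = np.empty((n_surrogates, n, n))
    rows = np.arange(T)
    for r in range(n_surrogates):
        shifts = rng.integers(min_shift, T - min_shift, size=n)
        idx = (rows[None, :] + shifts[:, None]) % T
        Es = np.exp(1j * np.take_along_axis(phases, idx, axis=1)[:, sl])
        # entry (i, j): PLF of unshifted channel i against shifted channel j
        surr[r] = np.abs(E0 @ Es.conj().T) / Tt
    order = np.sort(surr, axis=0)
    if per_pair:
        # one orientation per pair (upper triangle: the higher-index channel
        # is the shifted one), mirrored to keep the matrix symmetric
        thr = np.triu(order[n_surrogates - k_exceed], k=1)
        thr = thr + thr.T
    else:
        iu = np.triu_indices(n, k=1)
        pooled = np.sort(surr[:, iu[0], iu[1]].ravel())
        m = pooled.size
        thr_val = pooled[m - int(np.floor(alpha_level * (m + 1)))]
        thr = np.full((n, n), thr_val)
    np.fill_diagonal(thr, np.inf)  # self-pairs are never edges
    return thr


@dataclass
class NetworkConfig:
    n_surrogates: int = 99
    alpha_level: float = 0.05
    zero_lag_eps: float = 0.1      # rad, guard band around 0 and pi
    edge_fraction: float = 0.05    # trimmed from each end before PLF
    min_shift_s: float = 1.0
    per_pair: bool = True
    seed: int = 0


@dataclass
class FunctionalNetwork:
    """PLF-inferred functional network of one subject.

    ``adjacency[i, j] = 1`` iff the pair's PLF exceeds its surrogate
    threshold and its lag lies away from both 0 and pi.
    """

    plf: np.ndarray
    lag: np.ndarray
    sig_threshold: np.ndarray
    adjacency: np.ndarray
    labels: tuple
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        a = self.adjacency
        if not np.array_equal(a, a.T) or np.diag(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if ((self.plf < 0) | (self.plf > 1 + 1e-12)).any():
            raise ValueError("plf entries must lie in [0, 1]")
        if (a.astype(bool) & ~(self.plf > self.sig_threshold)).any():
            raise ValueError("adjacency contains an edge below its significance threshold")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self):
        """Edges as (label_a, label_b, plf, lag) tuples, upper triangle."""
        iu = np.triu_indices(self.n_nodes, k=1)
        out = []
        for i, j in zip(*iu):
            if self.adjacency[i, j]:
                out.append((self.labels[i], self.labels[j],
                            float(self.plf[i, j]), float(self.lag[i, j])))
        return out

    def to_graph(self):
        """The binary network as a :class:`networkx.Graph`."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for a, b, plf, lag in self.edge_list():
            g.add_edge(a, b, plf=plf, lag=lag)
        return g


def build_network(seg: EEGSegment, config: NetworkConfig | None = None) -> FunctionalNetwork:
    """Infer the functional network of a band-filtered segment.

    PLF and lags are estimated over all pairs, thresholds come from
    circular-shift surrogates, and pairs whose lag falls within
    ``zero_lag_eps`` of 0 or pi are excluded as putative volume conduction.
    """
    cfg = config or NetworkConfig()
    phases = instantaneous_phase(seg)
    plf, lag = plf_matrix(phases, cfg.edge_fraction)
    thr = surrogate_threshold(
        phases,
        n_surrogates=cfg.n_surrogates,
        alpha_level=cfg.alpha_level,
        min_shift_s=cfg.min_shift_s,
        sample_rate=seg.sample_rate,
        edge_fraction=cfg.edge_fraction,
        seed=cfg.seed,
        per_pair=cfg.per_pair,
    )
    abslag = np.abs(lag)
    lag_ok = (abslag > cfg.zero_lag_eps) & (abslag < np.pi - cfg.zero_lag_eps)
    adjacency = ((plf > thr) & lag_ok).astype(int)
    np.fill_diagonal(adjacency, 0)
    return FunctionalNetwork(
        plf=plf, lag=lag, sig_threshold=thr, adjacency=adjacency,
        labels=seg.channel_labels, config=cfg,
    )


def mean_degree(net: FunctionalNetwork) -> float:
    """Average number of edges per node — the scalar network biomarker."""
    return float(net.degrees().mean())
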