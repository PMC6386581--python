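"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis modules consume can be generated here with
known parameters, enabling recovery tests of the full pipeline:

- piecewise exponential-to-linear cell-growth trajectories, with an
  optional content-synthesis cap below the volume cap to produce
  cytoplasm dilution;
- 2-D fractional-Brownian GEM nanoparticle tracks with planted
  (K, alpha), synthesized by exact circulant embedding of fractional
  Gaussian noise;
- negative-binomial spike-in count matrices with scaling and
  non-scaling gene classes and embedded stress-response gene sets;
- noisy two-fluid buoyant-mass pairs;
- step-induction reporter traces with field background and per-cell
  autofluorescence.

All generators are pure functions of their parameter record, seed
included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gems import Track
from .growth import GrowthTrajectory
from .induction import InductionTrace
from .rnaseq import CountMatrix
from .smr import BuoyantPair

__all__ = [
    "GrowthParams",
    "FbmParams",
    "SpikeinSimParams",
    "InductionSimParams",
    "gen_growth_trajectory",
    "gen_fbm_tracks",
    "gen_spikein_counts",
    "gen_buoyant_pairs",
    "gen_induction_traces",
]


# ---------------------------------------------------------------- growth


@dataclass(frozen=True)
class GrowthParams:
    """Two-regime growth simulation parameters.

    Volume grows exponentially at rate ``k_exp`` until it reaches
    ``ploidy * V_star``, then linearly at the constant rate the
    exponential had at the transition.  Defaults follow newborn G1
    cells released into a prolonged arrest: 30 fL start, ~0.46/h
    specific rate, 200 fL haploid transition.
    """

    V0: float = 30.0  # fL
    k_exp: float = 0.46  # 1/h
    V_star: float = 200.0  # fL
    ploidy: int = 1
    noise_cv: float = 0.0
    dt: float = 0.25  # h
    duration: float = 7.0  # h
    content_cap_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.V0)
            and self.V0 > 0
            and np.isfinite(self.k_exp)
            and self.k_exp > 0
            and np.isfinite(self.V_star)
        ):
            raise ValueError("V0, k_exp, V_star must be finite and positive")
        if self.V_star <= self.V0:
            raise ValueError("V_star must exceed V0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 < self.content_cap_factor <= 1:
            raise ValueError("content_cap_factor must be in (0, 1]")


def _exp_then_linear(t: np.ndarray, v0: float, k: float, cap: float):
    """Closed-form dX/dt = k*X below cap, k*cap above; continuous."""
    t_cross = np.log(cap / v0) / k if cap > v0 else 0.0
    x = np.where(
        t <= t_cross,
        v0 * np.exp(k * t),
        cap + k * cap * (t - t_cross),
    )
    return x


def gen_growth_trajectory(p: GrowthParams) -> GrowthTrajectory:
    """Simulate one volume + content growth trajectory.

    Volume follows dV/dt = k_exp*V below ploidy*V_star and a constant
    dV/dt = k_exp*ploidy*V_star above, continuous at the transition.
    ``protein`` and ``RNA`` content tracks follow the same law but
    with their synthesis ceiling multiplied by ``content_cap_factor``;
    a factor < 1 makes content saturate earlier than volume, producing
    dilution.  Multiplicative lognormal noise with the given CV is
    applied independently per time point and track.
    """
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    cap_v = p.ploidy * p.V_star
    v = _exp_then_linear(t, p.V0, p.k_exp, cap_v)
    cap_c = p.content_cap_factor * cap_v
    c = _exp_then_linear(t, p.V0, p.k_exp, cap_c)
    content = {"protein": c.copy(), "RNA": c.copy()}
    if p.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + p.noise_cv**2))
        # unit-mean lognormal factors so noise is bias-free
        v = v * rng.lognormal(-(sigma**2) / 2, sigma, size=t.size)
        for k in content:
            content[k] = content[k] * rng.lognormal(
                -(sigma**2) / 2, sigma, size=t.size
            )
    return GrowthTrajectory(t=t, V=v, content=content)


# ------------------------------------------------------------------ fBm


@dataclass(frozen=True)
class FbmParams:
    """Fractional-Brownian GEM track simulation parameters.

    ``K`` and ``alpha`` are the planted anomalous-diffusion parameters
    of the 2-D ensemble MSD ``4*K*tau**alpha`` (per coordinate
    ``2*K*tau**alpha``).  The default frame interval of 0.01 s is an
    assumption — typical for GEM imaging but not dictated by any
    measurement — and should be set explicitly when it matters.
    """

    n_tracks: int = 100
    n_frames: int = 100
    dt: float = 0.01  # s
    K: float = 0.01  # um^2/s^alpha
    alpha: float = 0.9
    loc_noise_sd: float = 0.0  # um, per frame per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.n_tracks < 1 or self.dt <= 0 or self.loc_noise_sd < 0:
            raise ValueError("invalid track-count, dt or noise parameter")


def _fgn_autocov(m: int, hurst: float, sigma2: float) -> np.ndarray:
    k = np.arange(m, dtype=float)
    h2 = 2.0 * hurst
    return (
        sigma2
        / 2.0
        * (
            np.abs(k + 1) ** h2
            - 2.0 * np.abs(k) ** h2
            + np.abs(k - 1) ** h2
        )
    )


def _sample_fgn(
    n_seq: int, m: int, hurst: float, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact fractional Gaussian noise, shape (n_seq, m).

    Circulant embedding (Davies-Harte): the autocovariance is embedded
    in a circulant matrix whose eigenvalues come from one FFT; complex
    normal draws weighted by sqrt(eigenvalue/M) then yield two
    independent exact samples per row (real and imaginary parts).
    Falls back to a full-covariance Cholesky factorization if the
    embedding is not non-negative definite (short tracks).
    """
    r = _fgn_autocov(m, hurst, sigma2)
    if m == 1:
        return rng.normal(0.0, np.sqrt(sigma2), size=(n_seq, 1))
    c = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-9 * lam.max():
        cov = np.empty((m, m))
        idx = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        cov[:] = r[idx]
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((n_seq, m)) @ chol.T
    lam = np.clip(lam, 0.0, None)
    big_m = c.size
    n_half = (n_seq + 1) // 2
    z = rng.standard_normal((n_half, big_m)) + 1j * rng.standard_normal(
        (n_half, big_m)
    )
    y = np.fft.fft(z * np.sqrt(lam / big_m), axis=1)
    out = np.empty((2 * n_half, m))
    out[0::2] = y.real[:, :m]
    out[1::2] = y.imag[:, :m]
    return out[:n_seq]


def gen_fbm_tracks(p: FbmParams) -> list[Track]:
    """Simulate 2-D fractional-Brownian nanoparticle tracks.

    Each coordinate is exact fractional Gaussian noise cumulated so a
    noiseless track has ensemble MSD ``2*K*tau**alpha`` per coordinate
    (``4*K*tau**alpha`` in 2-D); independent Gaussian localization
    error of sd ``loc_noise_sd`` is added per frame per coordinate.
    """
    rng = np.random.default_rng(p.seed)
    m = p.n_frames - 1
    hurst = p.alpha / 2.0
    sigma2 = 2.0 * p.K * p.dt**p.alpha  # per-coordinate step variance
    incr = _sample_fgn(2 * p.n_tracks, m, hurst, sigma2, rng)
    pos = np.concatenate(
        [np.zeros((2 * p.n_tracks, 1)), np.cumsum(incr, axis=1)], axis=1
    )
    if p.loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, p.loc_noise_sd, size=pos.shape)
    t = np.arange(p.n_frames) * p.dt
    return [
        Track(id=f"track{i:05d}", t=t, x=pos[2 * i], y=pos[2 * i + 1])
        for i in range(p.n_tracks)
    ]


# --------------------------------------------------------------- spike-in


@dataclass(frozen=True)
class SpikeinSimParams:
    """Spike-in count-matrix simulation parameters.

    Emulates equal numbers of differently-sized cells mixed with a
    constant number of spike cells: a ``frac_scaling`` fraction of
    genes has expected per-cell abundance proportional to the sample's
    volume factor, the rest stay constant.  Stress-response member
    genes additionally shift up (induced) or down (repressed) in the
    late half of the samples.  Counts are negative binomial with
    variance ``mu + dispersion*mu**2``.
    """

    n_genes: int = 2000
    sample_volumes: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    frac_scaling: float = 0.8
    dispersion: float = 0.05
    spike_depth: int = 1_000_000
    esr_induced_size: int = 50
    esr_repressed_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sample_volumes):
            raise ValueError("sample volume factors must be positive")
        if not 0 <= self.frac_scaling <= 1:
            raise ValueError("frac_scaling must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.spike_depth <= 0:
            raise ValueError("spike_depth must be positive")
        if self.esr_induced_size + self.esr_repressed_size > self.n_genes:
            raise ValueError("fewer genes than the requested ESR set sizes")


#: Planted log2 shift of stress-response genes in late samples.
ESR_SHIFT_LOG2 = 2.0


def gen_spikein_counts(
    p: SpikeinSimParams,
) -> tuple[CountMatrix, dict[str, pd.DataFrame]]:
    """Simulate a spike-in normalized RNA-seq experiment.

    Returns the count matrix (with gene lengths, constant per-sample
    spike totals and sample volume factors) and a truth dict:
    ``labels`` (per gene: scaling flag, esr membership) and
    ``expected`` (planted expected fpkmCa per gene per sample).
    """
    rng = np.random.default_rng(p.seed)
    genes = pd.Index([f"gene{i:05d}" for i in range(p.n_genes)], name="gene")
    samples = pd.Index(
        [f"s{i}_v{v:g}" for i, v in enumerate(p.sample_volumes)], name="sample"
    )
    lengths = pd.Series(
        rng.integers(500, 5001, size=p.n_genes), index=genes, name="length_bp"
    )
    base = pd.Series(
        rng.lognormal(mean=np.log(20.0), sigma=1.0, size=p.n_genes),
        index=genes,
    )
    n_scaling = int(round(p.frac_scaling * p.n_genes))
    scaling = np.zeros(p.n_genes, dtype=bool)
    scaling[rng.choice(p.n_genes, size=n_scaling, replace=False)] = True

    esr = np.array([""] * p.n_genes, dtype=object)
    members = rng.choice(
        p.n_genes,
        size=p.esr_induced_size + p.esr_repressed_size,
        replace=False,
    )
    esr[members[: p.esr_induced_size]] = "induced"
    esr[members[p.esr_induced_size :]] = "repressed"

    vols = np.asarray(p.sample_volumes, dtype=float)
    expected = np.outer(base, np.ones_like(vols))
    expected[scaling] = np.outer(base[scaling], vols)
    late = np.arange(vols.size) >= vols.size - vols.size // 2
    shift = 2.0**ESR_SHIFT_LOG2
    expected[np.ix_(esr == "induced", late)] *= shift
    expected[np.ix_(esr == "repressed", late)] /= shift

    # forward model: count mean from fpkmCa, gene length and spike depth
    mu = (
        expected
        * (lengths.to_numpy()[:, None] / 1000.0)
        * (p.spike_depth / 1e6)
    )
    if p.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / p.dispersion
        counts = rng.negative_binomial(
            n_param, n_param / (n_param + mu)
        )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        lengths=lengths,
        spike_reads=pd.Series(p.spike_depth, index=samples, name="spike_reads"),
        volumes=pd.Series(vols, index=samples, name="volume"),
    )
    truth = {
        "labels": pd.DataFrame({"scaling": scaling, "esr": esr}, index=genes),
        "expected": pd.DataFrame(expected, index=genes, columns=samples),
    }
    return cm, truth


# ------------------------------------------------------------------- SMR


def gen_buoyant_pairs(
    n: int,
    density_range: tuple[float, float] = (1.05, 1.15),
    volume_range: tuple[float, float] = (30.0, 600.0),
    fluid1: float = 1.000,
    fluid2: float = 1.050,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[BuoyantPair], pd.DataFrame]:
    """Simulate two-fluid buoyant-mass pairs with known cell truth.

    ``m_b,i = V*(rho - rho_fluid,i) + N(0, noise_sd)`` pg.  Returns the
    pairs and a truth table (mass, volume, density per cell).
    """
    if fluid1 == fluid2:
        raise ValueError("the two fluid densities must differ")
    rng = np.random.default_rng(seed)
    vol = rng.uniform(*volume_range, size=n)
    rho = rng.uniform(*density_range, size=n)
    mb1 = vol * (rho - fluid1) + rng.normal(0.0, noise_sd, size=n)
    mb2 = vol * (rho - fluid2) + rng.normal(0.0, noise_sd, size=n)
    pairs = [
        BuoyantPair(m_b1=mb1[i], m_b2=mb2[i], rho_f1=fluid1, rho_f2=fluid2)
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {"mass": rho * vol, "volume": vol, "density": rho},
        index=[f"cell{i:05d}" for i in range(n)],
    )
    return pairs, truth


# -------------------------------------------------------------- induction


@dataclass(frozen=True)
class InductionSimParams:
    """Step-induction reporter-trace simulation parameters.

    Raw signal = field background + per-cell autofluorescence +
    ``min(rate*(t - t_on), amplitude)`` (0 before ``t_on``) + Gaussian
    noise.  ``t_on`` must leave at least 3 pre-induction frames for the
    baseline correction.
    """

    n_cells: int = 50
    t_on: float = 30.0  # min
    rate: float = 2.0  # a.u./min
    amplitude: float = 100.0  # a.u.
    background: float = 50.0  # a.u.
    autofluorescence: float = 20.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    dt: float = 3.0  # min
    duration: float = 120.0  # min

    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_on < 3 * self.dt:
            raise ValueError("t_on must allow at least 3 baseline frames")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.n_cells < 1 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("invalid n_cells, dt or duration")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("noise_sd and amplitude must be non-negative")


def gen_induction_traces(
    p: InductionSimParams,
) -> tuple[list[InductionTrace], np.ndarray]:
    """Simulate reporter-induction traces plus the field-background series.

    The field background drifts slowly (deterministic sinusoid around
    the nominal level); each cell draws its own constant
    autofluorescence.  Returns the raw traces (uncorrected) and the
    shared background series.
    """
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    background = p.background * (
        1.0 + 0.05 * np.sin(2.0 * np.pi * t / p.duration)
    )
    induction = np.clip(p.rate * (t - p.t_on), 0.0, p.amplitude)
    autofl = p.autofluorescence * rng.uniform(0.5, 1.5, size=p.n_cells)
    traces = []
    for i in range(p.n_cells):
        noise = (
            rng.normal(0.0, p.noise_sd, size=t.size) if p.noise_sd > 0 else 0.0
        )
        raw = background + autofl[i] + induction + noise
        traces.append(
            InductionTrace(
                cell_id=f"cell{i:04d}",
                t=t,
                raw=raw,
                field_background=background,
            )
        )
    return traces, background
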