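"""Synthetic OTU cohorts with planted guild structure.

Counts follow a logistic-normal multinomial model: per sample, a latent
Gaussian vector is drawn from a block covariance (one block per planted
guild, with condition-specific within-block correlation), mapped to a
composition by softmax, and realised as multinomial counts at a
negative-binomial sequencing depth.  This makes the correlation structure
seen by CLR/Spearman network inference directly plantable, along with
condition-specific guild abundance shifts and transitional "grey"
samples that interpolate the two condition profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_data import OtuTable, SampleMetadata, clr_transform, relative_abundance

__all__ = [
    "GuildSpec",
    "SyntheticCohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_grey_samples",
    "generate_paired_offspring",
    "calibrate_abundance_shift",
    "write_ground_truth",
]


@dataclass(frozen=True)
class GuildSpec:
    """Planted guild structure of the latent Gaussian layer."""

    sizes: tuple[int, ...]
    rho_intra_case: tuple[float, ...]
    rho_intra_control: tuple[float, ...]
    rho_inter: float = 0.0
    abundance_log_shift: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in np.atleast_1d(self.sizes))
        k = len(sizes)

        def _vec(x, name):
            arr = np.atleast_1d(np.asarray(x, dtype=float))
            if arr.size == 1:
                arr = np.repeat(arr, k)
            if arr.size != k:
                raise ValueError(f"{name} must have one entry per guild")
            return tuple(float(v) for v in arr)

        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "rho_intra_case", _vec(self.rho_intra_case, "rho_intra_case"))
        object.__setattr__(
            self, "rho_intra_control", _vec(self.rho_intra_control, "rho_intra_control")
        )
        shift = self.abundance_log_shift if len(np.atleast_1d(self.abundance_log_shift)) else 0.0
        object.__setattr__(self, "abundance_log_shift", _vec(shift, "abundance_log_shift"))
        if any(s < 2 for s in sizes):
            raise ValueError("guild sizes must be >= 2")
        for r in (*self.rho_intra_case, *self.rho_intra_control, self.rho_inter):
            if not -1 < r < 1:
                raise ValueError("correlations must lie strictly inside (-1, 1)")

    @property
    def n_guild_otus(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_case: int = 100
    n_control: int = 100
    n_grey: int = 0
    n_noise_otus: int = 50
    depth_mean: float = 30_000.0
    depth_dispersion: float = 10.0  # negative-binomial shape; larger = tighter
    grey_lambda_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_grey, self.n_noise_otus) < 0:
            raise ValueError("sample/OTU counts must be non-negative")
        lo, hi = self.grey_lambda_range
        if not (0 < lo <= hi < 1):
            raise ValueError("grey_lambda_range must lie inside (0, 1)")


@dataclass
class GroundTruth:
    """Generation-time labels: guild membership, sample states, planted OR."""

    membership: dict[str, str]  # otu_id -> "guild<k>" or "noise"
    sample_state: dict[str, dict]  # sample_id -> {"state": ..., "lambda": ...}
    planted_or: float | None = None

    def guild_members(self, guild: int) -> list[str]:
        tag = f"guild{guild}"
        return sorted(o for o, g in self.membership.items() if g == tag)


# ---------------------------------------------------------------------------
# Latent model internals
# ---------------------------------------------------------------------------

def _block_covariance(guilds: GuildSpec, n_noise: int, condition: str) -> np.ndarray:
    rhos = (
        guilds.rho_intra_case if condition == "case" else guilds.rho_intra_control
    )
    dim = guilds.n_guild_otus + n_noise
    cov = np.full((dim, dim), guilds.rho_inter)
    start = 0
    for size, rho in zip(guilds.sizes, rhos):
        cov[start : start + size, start : start + size] = rho
        start += size
    np.fill_diagonal(cov, 1.0)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent covariance is not positive definite") from exc
    return cov


def _latent_means(
    guilds: GuildSpec, n_noise: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shared baseline latent mean plus per-guild case shift."""
    dim = guilds.n_guild_otus + n_noise
    base = rng.normal(0.0, 1.0, size=dim)
    mu_control = base
    mu_case = base.copy()
    start = 0
    for size, shift in zip(guilds.sizes, guilds.abundance_log_shift):
        mu_case[start : start + size] += shift
        start += size
    return mu_case, mu_control


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _nb_depths(spec: SyntheticCohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    # Gamma-Poisson mixture = negative binomial with mean depth_mean.
    shape = spec.depth_dispersion
    lam = rng.gamma(shape, spec.depth_mean / shape, size=n)
    return np.maximum(rng.poisson(lam), 1)


def _sample_counts(
    mus: np.ndarray, chols: np.ndarray, depths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw multinomial counts for latent means/cholesky factors per sample."""
    n, dim = mus.shape
    counts = np.empty((n, dim), dtype=np.int64)
    normals = rng.standard_normal((n, dim))
    for i in range(n):
        z = mus[i] + chols[i] @ normals[i]
        counts[i] = rng.multinomial(depths[i], _softmax(z))
    return counts


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_cohort(
    guilds: GuildSpec, cohort: SyntheticCohortSpec
) -> tuple[OtuTable, list[SampleMetadata], GroundTruth]:
    """Generate a full case/control (+ optional grey) cohort.

    All randomness flows from ``cohort.seed``; identical specs give
    byte-identical outputs.  Grey samples interpolate the case and
    control latent means (and covariances) with a per-sample mixing
    weight drawn from ``grey_lambda_range``; their binary condition label
    is case when the weight is >= 0.5.
    """
    rng = np.random.default_rng(cohort.seed)
    n_noise = cohort.n_noise_otus
    dim = guilds.n_guild_otus + n_noise
    cov_case = _block_covariance(guilds, n_noise, "case")
    cov_control = _block_covariance(guilds, n_noise, "control")
    chol_case = np.linalg.cholesky(cov_case)
    chol_control = np.linalg.cholesky(cov_control)
    mu_case, mu_control = _latent_means(guilds, n_noise, rng)

    n_total = cohort.n_case + cohort.n_control + cohort.n_grey
    lambdas = rng.uniform(*cohort.grey_lambda_range, size=cohort.n_grey)

    mus = np.empty((n_total, dim))
    chols = np.empty((n_total, dim, dim))
    states: list[dict] = []
    mus[: cohort.n_case] = mu_case
    chols[: cohort.n_case] = chol_case
    states += [{"state": "case"}] * cohort.n_case
    sl = slice(cohort.n_case, cohort.n_case + cohort.n_control)
    mus[sl] = mu_control
    chols[sl] = chol_control
    states += [{"state": "control"}] * cohort.n_control
    for k, lam in enumerate(lambdas):
        i = cohort.n_case + cohort.n_control + k
        mus[i] = lam * mu_case + (1 - lam) * mu_control
        mix_cov = lam * cov_case + (1 - lam) * cov_control
        chols[i] = np.linalg.cholesky(mix_cov)
        states.append({"state": "grey", "lambda": float(lam)})

    depths = _nb_depths(cohort, n_total, rng)
    counts = _sample_counts(mus, chols, depths, rng)

    width = max(4, len(str(n_total)))
    sample_ids = tuple(f"S{i + 1:0{width}d}" for i in range(n_total))
    otu_ids = tuple(f"OTU_{j + 1:04d}" for j in range(dim))
    table = OtuTable(sample_ids, otu_ids, counts)

    membership: dict[str, str] = {}
    start = 0
    for g, size in enumerate(guilds.sizes):
        for j in range(start, start + size):
            membership[otu_ids[j]] = f"guild{g}"
        start += size
    for j in range(start, dim):
        membership[otu_ids[j]] = "noise"

    metadata: list[SampleMetadata] = []
    sample_state: dict[str, dict] = {}
    for sid, st in zip(sample_ids, states):
        sample_state[sid] = st
        if st["state"] == "grey":
            cond = "case" if st["lambda"] >= 0.5 else "control"
        else:
            cond = st["state"]
        metadata.append(SampleMetadata(sample_id=sid, condition=cond, cohort="synthetic"))

    truth = GroundTruth(membership=membership, sample_state=sample_state)
    return table, metadata, truth


def generate_grey_samples(
    guilds: GuildSpec, cohort: SyntheticCohortSpec
) -> tuple[OtuTable, list[SampleMetadata], GroundTruth]:
    """Generate only the transitional (grey) samples of a cohort spec."""
    if cohort.n_grey <= 0:
        raise ValueError("n_grey must be positive")
    grey_only = SyntheticCohortSpec(
        n_case=0,
        n_control=0,
        n_grey=cohort.n_grey,
        n_noise_otus=cohort.n_noise_otus,
        depth_mean=cohort.depth_mean,
        depth_dispersion=cohort.depth_dispersion,
        grey_lambda_range=cohort.grey_lambda_range,
        seed=cohort.seed,
    )
    return generate_cohort(guilds, grey_only)


def generate_paired_offspring(
    maternal: OtuTable, transmission_weight: float, seed: int = 0
) -> OtuTable:
    """Offspring tables whose latent profile mixes the maternal one.

    offspring latent = w * maternal latent + (1 - w) * independent draw,
    where the maternal latent is the CLR of the maternal counts and the
    independent component is Gaussian with the maternal latents' per-OTU
    mean and standard deviation.  Counts are re-drawn multinomially at
    each maternal sample's depth.
    """
    if not 0 <= transmission_weight <= 1:
        raise ValueError("transmission_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    latent = clr_transform(maternal, pseudocount=0.5)
    mu = latent.mean(axis=0)
    sd = latent.std(axis=0)
    indep = mu + sd * rng.standard_normal(latent.shape)
    mixed = transmission_weight * latent + (1 - transmission_weight) * indep
    depths = maternal.depths()
    counts = np.empty_like(maternal.counts)
    probs = _softmax(mixed)
    for i in range(maternal.n_samples):
        counts[i] = rng.multinomial(depths[i], probs[i])
    offspring_ids = tuple(f"{sid}_offspring" for sid in maternal.sample_ids)
    return OtuTable(offspring_ids, maternal.otu_ids, counts, maternal.taxonomy)


# ---------------------------------------------------------------------------
# Calibration of the planted odds ratio
# ---------------------------------------------------------------------------

def _simulated_or(
    shift: float,
    guilds: GuildSpec,
    guild: int,
    mu_control: np.ndarray,
    noise_case: np.ndarray,
    noise_control: np.ndarray,
) -> float:
    """OR at the pooled median split of latent-level guild abundance.

    ``noise_*`` are pre-drawn correlated latent residuals (n x dim), so
    the shift -> OR map is deterministic and monotone for bisection.
    """
    start = sum(guilds.sizes[:guild])
    members = slice(start, start + guilds.sizes[guild])
    mu_case = mu_control.copy()
    mu_case[members] += shift
    ab_case = _softmax(mu_case + noise_case)[:, members].sum(axis=1)
    ab_ctrl = _softmax(mu_control + noise_control)[:, members].sum(axis=1)
    n_per_arm = ab_case.shape[0]
    med = np.median(np.concatenate([ab_case, ab_ctrl]))
    a = np.sum(ab_case > med)
    b = np.sum(ab_ctrl > med)
    c = n_per_arm - a
    d = n_per_arm - b
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def calibrate_abundance_shift(
    target_or: float,
    guilds: GuildSpec,
    cohort: SyntheticCohortSpec,
    guild: int = 0,
    n_sim: int = 4000,
    seed: int = 12345,
    tol: float = 0.02,
) -> float:
    """Find the latent log shift whose median-split OR matches a target.

    Bisection on the (monotone) shift -> OR map, evaluated by simulating
    ``n_sim`` samples per arm at the latent level.  The returned shift
    can be planted via ``GuildSpec.abundance_log_shift``.
    """
    if target_or <= 1:
        raise ValueError("target OR must exceed 1 for an upward shift")
    rng = np.random.default_rng(seed)
    n_noise = cohort.n_noise_otus
    chol_case = np.linalg.cholesky(_block_covariance(guilds, n_noise, "case"))
    chol_control = np.linalg.cholesky(_block_covariance(guilds, n_noise, "control"))
    _, mu_control = _latent_means(guilds, n_noise, np.random.default_rng(cohort.seed))
    dim = mu_control.size
    noise_case = (chol_case @ rng.standard_normal((dim, n_sim))).T
    noise_control = (chol_control @ rng.standard_normal((dim, n_sim))).T

    def f(shift: float) -> float:
        return _simulated_or(
            shift, guilds, guild, mu_control, noise_case, noise_control
        )

    lo, hi = 0.0, 0.5
    while f(hi) < target_or:
        hi *= 2.0
        if hi > 16:
            raise RuntimeError("cannot bracket the target odds ratio")
    for _ in range(40):
        mid = (lo + hi) / 2.0
        value = f(mid)
        if abs(value - target_or) < tol * target_or:
            return mid
        if value < target_or:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "membership": truth.membership,
                "sample_state": truth.sample_state,
                "planted_or": truth.planted_or,
            },
            fh,
            indent=2,
        )


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return GroundTruth(
        membership=doc["membership"],
        sample_state=doc["sample_state"],
        planted_or=doc.get("planted_or"),
    )
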