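"""Synthetic isotope communities with the structure the analysis assumes.

Species are bivariate-normal clouds in the (d13C, d15N) plane described by a
mean, a spread and a sample size.  Published species tables usually print a
mean with a min-max range rather than an SD; the generator converts a range
to an SD as range/4 (+/- 2 SD spans the range), overridable by giving the SD
directly.  Each community carries a raw baseline offset added to every
sample, emulating ecosystems whose raw isotope scales differ — exactly what
baseline standardization must remove.

``arreo_fixture`` builds the package's worked example: a Mediterranean lake
community of four non-native consumers over a *Phragmites australis*
macrophyte baseline, plus three donor ecosystems each holding one extirpated
native species (tench, European eel, whirligig beetle) sampled elsewhere at
a shifted raw baseline.  Means, ranges and sample sizes follow the published
species table for that system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CommunityDataset, IsotopeSample, SpeciesGroup
from .mixing import SourceSpec

__all__ = [
    "SpeciesSpec",
    "CommunitySpec",
    "MixtureScenario",
    "generate_community",
    "arreo_fixture",
    "mixture_scenario",
    "ARREO_SPECS",
    "DONOR_SPECS",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One species' cloud: mean, spread (sd or min-max range) and n."""

    species: str
    mean: tuple[float, float]  # (d13C, d15N) permil
    n: int
    sd: tuple[float, float] | None = None
    range_: tuple[tuple[float, float], tuple[float, float]] | None = None  # ((Cmin,Cmax),(Nmin,Nmax))
    role: str = "consumer"
    tissue: str = ""
    corr: float = 0.0  # optional C-N correlation; 0 (diagonal) by default

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"{self.species}: n must be >= 1")
        if (self.sd is None) == (self.range_ is None):
            raise ValueError(f"{self.species}: give exactly one of sd or range_")
        if not -1.0 < self.corr < 1.0:
            raise ValueError("corr must lie in (-1, 1)")

    @property
    def sigma(self) -> tuple[float, float]:
        """SD per element; a printed min-max range maps to range/4."""
        if self.sd is not None:
            return self.sd
        (cmin, cmax), (nmin, nmax) = self.range_
        return ((cmax - cmin) / 4.0, (nmax - nmin) / 4.0)


@dataclass(frozen=True)
class CommunitySpec:
    ecosystem: str
    species_specs: tuple[SpeciesSpec, ...]
    baseline_offset: tuple[float, float] = (0.0, 0.0)  # raw (d13C, d15N) shift
    seed: int | None = None

    def __post_init__(self):
        baselines = [s for s in self.species_specs if s.role == "baseline"]
        if len(baselines) != 1:
            raise ValueError(
                f"{self.ecosystem}: exactly one baseline species required, "
                f"got {len(baselines)}"
            )


def generate_community(spec: CommunitySpec) -> CommunityDataset:
    """Draw the community: per species, n bivariate-normal samples.

    A pure function of (spec, seed): identical reruns are identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    offC, offN = spec.baseline_offset
    groups: dict[str, SpeciesGroup] = {}
    baseline = None
    for sp in spec.species_specs:
        sC, sN = sp.sigma
        cov = np.array(
            [[sC**2, sp.corr * sC * sN], [sp.corr * sC * sN, sN**2]]
        )
        xy = rng.multivariate_normal(
            [sp.mean[0] + offC, sp.mean[1] + offN], cov, size=sp.n,
            method="cholesky" if min(sC, sN) > 0 else "svd",
        )
        samples = [
            IsotopeSample(
                species=sp.species,
                ecosystem=spec.ecosystem,
                role=sp.role,
                d13C=float(c),
                d15N=float(n15),
                tissue=sp.tissue,
            )
            for c, n15 in xy
        ]
        groups[sp.species] = SpeciesGroup(sp.species, samples)
        if sp.role == "baseline":
            baseline = sp.species
    return CommunityDataset(
        ecosystem=spec.ecosystem, groups=groups, baseline_species=baseline
    )


# Published per-species summaries (standardized scale): mean (min-max), n.
ARREO_SPECS: tuple[SpeciesSpec, ...] = (
    SpeciesSpec("M. salmoides", mean=(-2.2, 6.8), n=15,
                range_=((-3.1, -0.9), (5.8, 7.9)), tissue="caudal muscle"),
    SpeciesSpec("L. gibbosus", mean=(-3.6, 5.1), n=15,
                range_=((-4.7, 1.4), (3.5, 7.3)), tissue="caudal muscle"),
    SpeciesSpec("C. carpio", mean=(-5.3, 3.8), n=11,
                range_=((-7.1, -3.5), (2.6, 5.5)), tissue="caudal muscle"),
    SpeciesSpec("P. clarkii", mean=(0.4, 1.0), n=15,
                range_=((-3.1, 5.2), (-1.5, 3.3)), tissue="tail muscle"),
    SpeciesSpec("P. australis", mean=(-0.0, 0.0), n=5,
                range_=((-0.7, 0.6), (-0.4, 0.6)), role="baseline",
                tissue="pooled leaves"),
)

DONOR_SPECS: dict[str, SpeciesSpec] = {
    "T. tinca": SpeciesSpec("T. tinca", mean=(-2.9, 4.7), n=26,
                            range_=((-4.3, -1.2), (3.9, 5.4)),
                            tissue="caudal muscle"),
    "A. anguilla": SpeciesSpec("A. anguilla", mean=(-4.7, 6.0), n=45,
                               range_=((-6.3, -3.0), (4.4, 7.5)),
                               tissue="caudal muscle"),
    "Gyrinus sp.": SpeciesSpec("Gyrinus sp.", mean=(0.2, -4.9), n=17,
                               range_=((-3.6, 3.6), (-6.0, -3.8)),
                               tissue="whole organism"),
}

_DONOR_ECOSYSTEMS = {
    "T. tinca": ("England small ponds", (-25.0, 10.5)),
    "A. anguilla": ("Grosser Vaetersee", (-28.5, 9.0)),
    "Gyrinus sp.": ("Ontario experimental lakes", (-26.0, 3.0)),
}

#: Raw baseline offset of the target lake (d13C, d15N); nonzero so
#: standardization is exercised nontrivially.
_ARREO_OFFSET = (-27.0, 8.0)

_BASELINE_SPEC = ARREO_SPECS[-1]  # macrophyte baseline, reused per ecosystem


def arreo_fixture(seed: int = 0) -> tuple[CommunityDataset, dict[str, CommunityDataset]]:
    """Target lake community plus one donor community per extirpated native.

    Every ecosystem gets its own macrophyte baseline group (same standardized
    spec, different raw offset), so the full standardize-then-superimpose
    pipeline can run end to end.  Deterministic in ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(1 + len(_DONOR_ECOSYSTEMS))
    target = generate_community(
        CommunitySpec(
            ecosystem="Arreo Lake",
            species_specs=ARREO_SPECS,
            baseline_offset=_ARREO_OFFSET,
            seed=int(seeds[0]) % (2**31),
        )
    )
    donors: dict[str, CommunityDataset] = {}
    for i, (species, (eco, offset)) in enumerate(_DONOR_ECOSYSTEMS.items()):
        donors[species] = generate_community(
            CommunitySpec(
                ecosystem=eco,
                species_specs=(DONOR_SPECS[species], _BASELINE_SPEC),
                baseline_offset=offset,
                seed=int(seeds[1 + i]) % (2**31),
            )
        )
    return target, donors


@dataclass(frozen=True)
class MixtureScenario:
    """Parameter-recovery harness output with its ground truth attached."""

    consumer: SpeciesGroup
    sources: tuple[SourceSpec, ...]
    proportions: tuple[float, ...]  # the generating truth


def mixture_scenario(
    proportions: tuple[float, ...] | list[float],
    sources: list[SourceSpec],
    n_consumers: int = 30,
    seed: int | None = None,
    residual_sd: tuple[float, float] = (0.0, 0.0),
    consumer_name: str = "synthetic consumer",
) -> MixtureScenario:
    """Consumers drawn from the mixing model at known proportions.

    Each consumer value is Normal(sum_k p_k (mean_k + tdf_k),
    sum_k p_k^2 (sd_k^2 + tdf_sd_k^2) + residual_sd^2) per isotope, i.e. the
    exact likelihood the mixing model fits, so posterior recovery of
    ``proportions`` is a well-posed check.
    """
    p = np.asarray(proportions, dtype=float)
    if len(p) != len(sources):
        raise ValueError("one proportion per source required")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must lie on the simplex")
    smean = np.array([s.mean for s in sources])
    tmean = np.array([s.tdf_mean for s in sources])
    var = (p[:, None] ** 2 * (np.array([s.sd for s in sources]) ** 2
                              + np.array([s.tdf_sd for s in sources]) ** 2)).sum(axis=0)
    var = var + np.asarray(residual_sd, dtype=float) ** 2
    mu = p @ (smean + tmean)
    rng = np.random.default_rng(seed)
    xy = mu + np.sqrt(var) * rng.standard_normal((n_consumers, 2))
    samples = [
        IsotopeSample(
            species=consumer_name, ecosystem="synthetic", role="consumer",
            d13C=float(c), d15N=float(n15),
        )
        for c, n15 in xy
    ]
    return MixtureScenario(
        consumer=SpeciesGroup(consumer_name, samples),
        sources=tuple(sources),
        proportions=tuple(float(v) for v in p),
    )
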