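"""Baseline vetting, mean-subtraction standardization and superimposition.

Cross-ecosystem comparison of isotope data requires expressing every
community on the scale of a shared baseline organism (here a macrophyte):
each individual's (d15N, d13C) is reduced by its own ecosystem's baseline
mean.  A donor ecosystem's standardized species can then be *superimposed*
into a standardized target community, emulating its (re)introduction.

Whether two ecosystems' baselines are comparable at all is vetted first, on
the raw data: the 95% t-confidence intervals of the baseline means must
intersect in both elements (closed intervals — touching endpoints count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import CommunityDataset, SpeciesGroup

__all__ = [
    "BaselineSummary",
    "BaselineComparability",
    "StandardizedCommunity",
    "IncomparableBaselineError",
    "baseline_summary",
    "check_baseline_comparability",
    "standardize_community",
    "superimpose",
]


class IncomparableBaselineError(ValueError):
    """Baselines fail the CI-overlap rule and superimposition was not forced."""


@dataclass(frozen=True)
class BaselineSummary:
    """Mean and t-based CI of a baseline taxon's isotope values (permil)."""

    species: str
    ecosystem: str
    mean_d15N: float
    mean_d13C: float
    ci95_d15N: tuple[float, float]
    ci95_d13C: tuple[float, float]
    n: int
    level: float = 0.95


@dataclass(frozen=True)
class BaselineComparability:
    donor: BaselineSummary
    target: BaselineSummary
    overlap_d15N: bool
    overlap_d13C: bool

    @property
    def verdict(self) -> str:
        return (
            "comparable" if (self.overlap_d15N and self.overlap_d13C)
            else "not_comparable"
        )


@dataclass
class StandardizedCommunity(CommunityDataset):
    """A community on the baseline-centered scale.

    The subtracted baseline means are kept for audit; the standardized
    baseline group itself has mean (0, 0) to numerical tolerance.  ``audit``
    accumulates superimposition provenance (species added, comparability
    verdicts).
    """

    baseline_mean_d15N: float = 0.0
    baseline_mean_d13C: float = 0.0
    audit: dict = field(default_factory=dict)


def baseline_summary(group: SpeciesGroup, level: float = 0.95) -> BaselineSummary:
    """Two-sided t-interval on each element's mean at the given level.

    A zero-variance group yields the degenerate interval ``[c, c]``.
    """
    if group.n < 2:
        raise ValueError(
            f"baseline summary needs n >= 2, got n={group.n} for {group.species!r}"
        )

    def ci(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1)) / np.sqrt(len(x))
        if se == 0.0:
            return (m, m)
        half = stats.t.ppf(0.5 + level / 2, df=len(x) - 1) * se
        return (m - half, m + half)

    return BaselineSummary(
        species=group.species,
        ecosystem=group.ecosystem,
        mean_d15N=float(np.mean(group.d15N)),
        mean_d13C=float(np.mean(group.d13C)),
        ci95_d15N=ci(group.d15N),
        ci95_d13C=ci(group.d13C),
        n=group.n,
        level=level,
    )


def check_baseline_comparability(
    donor: BaselineSummary, target: BaselineSummary
) -> BaselineComparability:
    """Comparable iff the two CIs intersect in *both* elements (closed rule)."""

    def overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    return BaselineComparability(
        donor=donor,
        target=target,
        overlap_d15N=overlap(donor.ci95_d15N, target.ci95_d15N),
        overlap_d13C=overlap(donor.ci95_d13C, target.ci95_d13C),
    )


def standardize_community(ds: CommunityDataset) -> StandardizedCommunity:
    """Subtract the baseline group's mean (d15N, d13C) from every sample.

    The operation is shift-invariant and idempotent: a community already on
    the baseline scale has baseline mean (0, 0) and passes through unchanged.
    A baseline with n = 1 is allowed (its mean is the single value).
    """
    if ds.baseline_species is None or ds.baseline_species not in ds.groups:
        raise KeyError(
            f"cannot standardize {ds.ecosystem!r}: baseline group missing"
        )
    base = ds.groups[ds.baseline_species]
    mN = float(np.mean(base.d15N))
    mC = float(np.mean(base.d13C))
    groups = {
        sp: SpeciesGroup(
            sp,
            [replace(s, d15N=s.d15N - mN, d13C=s.d13C - mC) for s in g.samples],
        )
        for sp, g in ds.groups.items()
    }
    return StandardizedCommunity(
        ecosystem=ds.ecosystem,
        groups=groups,
        baseline_species=ds.baseline_species,
        baseline_mean_d15N=mN,
        baseline_mean_d13C=mC,
        audit={"standardized_from": ds.ecosystem},
    )


def superimpose(
    target: StandardizedCommunity,
    donor: StandardizedCommunity,
    species: str,
    comparability: BaselineComparability | None = None,
    allow_incomparable: bool = False,
) -> StandardizedCommunity:
    """Insert the donor's standardized ``species`` group into ``target``.

    Resident groups are passed through untouched and the donor group's values
    are not re-centered; its samples are only re-flagged ``provenance=donor``.
    If a baseline-comparability check is supplied and failed, the operation
    refuses unless ``allow_incomparable`` is set, in which case the verdict is
    recorded in the audit trail instead (the no-shared-baseline situation,
    where a donor is standardized against the target's own baseline under
    stated caveats, is handled the same way).
    """
    if species in target.groups:
        raise ValueError(
            f"species {species!r} already present in target {target.ecosystem!r}"
        )
    if species not in donor.groups:
        raise KeyError(f"species {species!r} not found in donor {donor.ecosystem!r}")
    if (
        comparability is not None
        and comparability.verdict == "not_comparable"
        and not allow_incomparable
    ):
        raise IncomparableBaselineError(
            f"baselines of {donor.ecosystem!r} and {target.ecosystem!r} are not "
            "comparable (95% CIs disjoint); pass allow_incomparable=True to force"
        )

    g = donor.groups[species]
    moved = SpeciesGroup(
        species,
        [
            replace(s, ecosystem=target.ecosystem, provenance="donor")
            for s in g.samples
        ],
    )
    groups = dict(target.groups)
    groups[species] = moved
    audit = dict(target.audit)
    audit["superimposed"] = list(audit.get("superimposed", []))
    audit["superimposed"].append(
        {
            "species": species,
            "donor_ecosystem": donor.ecosystem,
            "comparability": (
                comparability.verdict if comparability is not None else "unchecked"
            ),
        }
    )
    return StandardizedCommunity(
        ecosystem=target.ecosystem,
        groups=groups,
        baseline_species=target.baseline_species,
        baseline_mean_d15N=target.baseline_mean_d15N,
        baseline_mean_d13C=target.baseline_mean_d13C,
        audit=audit,
    )
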