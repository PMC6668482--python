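"""Individual-based transposition–genetic-drift model of TE copy accumulation.

Simulates the accumulation of new transposable-element (TE) insertions in
selfing lines propagated by single-seed descent, starting from a single
active donor element.  Each generation, active copies transpose at a fixed
per-copy rate ``K`` (events per active allele per generation); each
transposition event creates one new insertion in the heterozygous state and
may excise its source allele with probability ``E`` (cut-and-paste without
gap repair, leaving a footprint).  Heterozygous loci then segregate under
selfing (1/4 fixed homozygous : 1/2 heterozygous : 1/4 lost).  Once the
copy number reaches a threshold ``l``, all copies of the family undergo
concerted epigenetic silencing and transposition stops permanently.

Two activity variants are modelled:

* ``master``     — only the donor element is mobile; daughter copies are inert.
* ``transposon`` — donor and daughter copies are equally mobile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TEModelParams",
    "LineState",
    "Trajectory",
    "ZygositySample",
    "TrajectoryStats",
    "copy_number",
    "step_generation",
    "simulate_lineage",
    "simulate_population",
    "trajectory_stats",
]

VARIANTS = ("master", "transposon")
COUNTING_MODES = ("total", "new_only")
ZYGOSITIES = ("homozygous", "heterozygous")

# Mendelian selfing outcome for one heterozygous locus.
P_FIX, P_HET, P_LOSS = 0.25, 0.5, 0.25


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TEModelParams:
    """Parameters of the transposition–drift model.

    Parameters
    ----------
    variant
        ``"master"`` (donor-only activity) or ``"transposon"`` (all copies
        active).
    K
        Transposition rate per active copy (allele) per generation.
    E
        Excision probability per transposition event.
    l
        Silencing threshold: copy number per diploid genome at which
        concerted silencing triggers.  ``math.inf`` (or ``None``) disables
        silencing.
    n_generations
        Number of selfing generations to simulate (generation 0 is the
        founder).
    donor_zygosity_at_start
        Whether the donor locus starts homozygous (two alleles) or
        heterozygous (one allele).
    counting
        Copy-count definition used for the silencing threshold:
        ``"new_only"`` counts new-insertion alleles only, ``"total"``
        includes the donor alleles.
    """

    variant: str = "transposon"
    K: float = 0.0
    E: float = 0.0
    l: float = math.inf
    n_generations: int = 6
    donor_zygosity_at_start: str = "homozygous"
    counting: str = "new_only"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not (self.K >= 0):
            raise ValueError(f"transposition rate K must be >= 0, got {self.K}")
        if not (0 <= self.E <= 1):
            raise ValueError(f"excision probability E must lie in [0, 1], got {self.E}")
        l = math.inf if self.l is None else float(self.l)
        object.__setattr__(self, "l", l)
        if not (l >= 1):
            raise ValueError(f"silencing threshold l must be >= 1 (or inf), got {self.l}")
        if math.isfinite(l) and l != int(l):
            raise ValueError(f"finite silencing threshold must be an integer, got {self.l}")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.donor_zygosity_at_start not in ZYGOSITIES:
            raise ValueError(f"donor_zygosity_at_start must be one of {ZYGOSITIES}")
        if self.counting not in COUNTING_MODES:
            raise ValueError(f"counting must be one of {COUNTING_MODES}")

    @property
    def initial_donor_alleles(self) -> int:
        return 2 if self.donor_zygosity_at_start == "homozygous" else 1


@dataclass(frozen=True)
class LineState:
    """Zygosity-stratified copy counts of one lineage at one generation."""

    generation: int = 0
    donor_alleles: int = 2
    n_hom: int = 0
    n_het: int = 0
    silenced: bool = False
    n_footprints: int = 0

    def __post_init__(self) -> None:
        if self.donor_alleles not in (0, 1, 2):
            raise ValueError("donor_alleles must be 0, 1 or 2")
        if min(self.n_hom, self.n_het, self.n_footprints, self.generation) < 0:
            raise ValueError("counts and generation must be non-negative")


def copy_number(state: LineState, counting: str = "total") -> int:
    """Diploid copy number of a line state.

    ``total`` counts every allele (2 per homozygous locus, 1 per
    heterozygous locus, plus donor alleles); ``new_only`` excludes the
    donor.
    """
    if counting not in COUNTING_MODES:
        raise ValueError(f"counting must be one of {COUNTING_MODES}")
    new = 2 * state.n_hom + state.n_het
    return new if counting == "new_only" else new + state.donor_alleles


@dataclass(frozen=True)
class Trajectory:
    """States of one lineage at generations 0..n, plus the seed used."""

    states: tuple[LineState, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.states]
        if gens != list(range(len(self.states))):
            raise ValueError("trajectory generations must be 0,1,2,...")

    @property
    def final(self) -> LineState:
        return self.states[-1]

    def copy_numbers(self, counting: str = "total") -> np.ndarray:
        return np.array([copy_number(s, counting) for s in self.states])


@dataclass(frozen=True)
class ZygositySample:
    """Per-line (n_hom, n_het) counts — the 2D sample fed to the Peacock test."""

    n_hom: np.ndarray
    n_het: np.ndarray
    line_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n_hom = np.asarray(self.n_hom, dtype=np.int64)
        n_het = np.asarray(self.n_het, dtype=np.int64)
        object.__setattr__(self, "n_hom", n_hom)
        object.__setattr__(self, "n_het", n_het)
        if n_hom.ndim != 1 or n_hom.shape != n_het.shape:
            raise ValueError("n_hom and n_het must be 1-D arrays of equal length")
        if n_hom.size == 0:
            raise ValueError("a zygosity sample must contain at least one line")
        if (n_hom < 0).any() or (n_het < 0).any():
            raise ValueError("zygosity counts must be non-negative")
        if self.line_ids is not None and len(self.line_ids) != n_hom.size:
            raise ValueError("line_ids length mismatch")

    def __len__(self) -> int:
        return int(self.n_hom.size)

    def as_array(self) -> np.ndarray:
        """(n, 2) array of (n_hom, n_het) pairs."""
        return np.column_stack([self.n_hom, self.n_het])

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "ZygositySample":
        arr = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# Generation step
#
# Sub-step order within one generation: transposition (with excision of the
# transposing source allele), then Mendelian segregation of every
# heterozygous locus (including loci created this generation), then the
# silencing check.  Copies created in generation t become active in t+1.
# ---------------------------------------------------------------------------


def _active_alleles(variant, donor, n_hom, n_het, silenced):
    if variant == "master":
        active = donor.copy()
    else:
        active = donor + 2 * n_hom + n_het
    active[silenced] = 0
    return active


def _apply_excisions(i, n_exc, variant, donor, n_hom, n_het, footprints, rng):
    """Excise up to ``n_exc`` source alleles of lineage ``i``, in place.

    The source of each excising event is drawn uniformly among the active
    alleles still present (donor alleles; under the transposon variant also
    the two alleles of each homozygous and the one allele of each
    heterozygous new locus).  Excising one allele of a homozygous locus
    leaves it heterozygous; excising a heterozygous or donor allele removes
    the locus/allele and leaves a footprint.
    """
    for _ in range(n_exc):
        d = int(donor[i])
        if variant == "master":
            if d == 0:
                break
            donor[i] = d - 1
            footprints[i] += 1
            continue
        h2 = 2 * int(n_hom[i])
        h1 = int(n_het[i])
        total = d + h2 + h1
        if total == 0:
            break
        r = int(rng.integers(total))
        if r < d:
            donor[i] = d - 1
            footprints[i] += 1
        elif r < d + h2:
            n_hom[i] -= 1
            n_het[i] += 1
        else:
            n_het[i] -= 1
            footprints[i] += 1


def _advance(params, donor, n_hom, n_het, silenced, footprints, rng):
    """Advance a population (parallel arrays over lineages) one generation, in place."""
    active = _active_alleles(params.variant, donor, n_hom, n_het, silenced)

    # Transposition: each active allele fires Poisson(K) events; every event
    # creates one new heterozygous insertion.
    n_events = rng.poisson(params.K * active) if params.K > 0 else np.zeros_like(active)

    # Excision of source alleles, at probability E per event.
    if params.E > 0 and n_events.any():
        n_exc = rng.binomial(n_events, params.E)
        for i in np.nonzero(n_exc)[0]:
            _apply_excisions(i, int(n_exc[i]), params.variant, donor, n_hom, n_het, footprints, rng)

    n_het += n_events

    # Mendelian segregation under selfing of all heterozygous loci.
    to_hom = rng.binomial(n_het, P_FIX)
    remaining = n_het - to_hom
    kept_het = rng.binomial(remaining, P_HET / (1.0 - P_FIX))
    n_hom += to_hom
    n_het[:] = kept_het

    # A heterozygous donor locus segregates like any other heterozygous locus.
    het_donor = np.nonzero(donor == 1)[0]
    if het_donor.size:
        u = rng.random(het_donor.size)
        donor[het_donor] = np.where(u < P_FIX, 2, np.where(u < P_FIX + P_HET, 1, 0))

    # Copy-number-triggered concerted silencing (permanent).
    if math.isfinite(params.l):
        cn = 2 * n_hom + n_het
        if params.counting == "total":
            cn = cn + donor
        silenced |= cn >= params.l


def step_generation(
    state: LineState, params: TEModelParams, rng: np.random.Generator | int | None
) -> LineState:
    """Advance one lineage by one selfing generation."""
    rng = _as_rng(rng)
    donor = np.array([state.donor_alleles], dtype=np.int64)
    n_hom = np.array([state.n_hom], dtype=np.int64)
    n_het = np.array([state.n_het], dtype=np.int64)
    silenced = np.array([state.silenced])
    footprints = np.array([state.n_footprints], dtype=np.int64)
    _advance(params, donor, n_hom, n_het, silenced, footprints, rng)
    return LineState(
        generation=state.generation + 1,
        donor_alleles=int(donor[0]),
        n_hom=int(n_hom[0]),
        n_het=int(n_het[0]),
        silenced=bool(silenced[0]),
        n_footprints=int(footprints[0]),
    )


def _initial_state(params: TEModelParams) -> LineState:
    state = LineState(generation=0, donor_alleles=params.initial_donor_alleles)
    if math.isfinite(params.l) and copy_number(state, params.counting) >= params.l:
        state = replace(state, silenced=True)
    return state


def simulate_lineage(
    params: TEModelParams, rng: np.random.Generator | int | None = None
) -> Trajectory:
    """Simulate one lineage for ``params.n_generations`` generations."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    states = [_initial_state(params)]
    for _ in range(params.n_generations):
        states.append(step_generation(states[-1], params, rng))
    return Trajectory(tuple(states), seed=seed)


def simulate_population(
    params: TEModelParams,
    n_lineages: int,
    rng: np.random.Generator | int | None = None,
    keep_trajectories: bool = True,
) -> tuple[ZygositySample, list[Trajectory]]:
    """Simulate ``n_lineages`` independent selfing lineages.

    All lineages are advanced in lock-step from a single seedable generator
    (vectorised array draws per generation), so a run is fully reproducible
    given the seed.  Returns the final-generation :class:`ZygositySample`
    and, unless ``keep_trajectories=False``, one :class:`Trajectory` per
    lineage.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)

    init = _initial_state(params)
    donor = np.full(n_lineages, init.donor_alleles, dtype=np.int64)
    n_hom = np.zeros(n_lineages, dtype=np.int64)
    n_het = np.zeros(n_lineages, dtype=np.int64)
    silenced = np.full(n_lineages, init.silenced)
    footprints = np.zeros(n_lineages, dtype=np.int64)

    record = [] if keep_trajectories else None
    if keep_trajectories:
        record.append((donor.copy(), n_hom.copy(), n_het.copy(), silenced.copy(), footprints.copy()))
    for _ in range(params.n_generations):
        _advance(params, donor, n_hom, n_het, silenced, footprints, rng)
        if keep_trajectories:
            record.append((donor.copy(), n_hom.copy(), n_het.copy(), silenced.copy(), footprints.copy()))

    sample = ZygositySample(n_hom.copy(), n_het.copy())
    trajectories: list[Trajectory] = []
    if keep_trajectories:
        for i in range(n_lineages):
            states = tuple(
                LineState(
                    generation=g,
                    donor_alleles=int(rec[0][i]),
                    n_hom=int(rec[1][i]),
                    n_het=int(rec[2][i]),
                    silenced=bool(rec[3][i]),
                    n_footprints=int(rec[4][i]),
                )
                for g, rec in enumerate(record)
            )
            trajectories.append(Trajectory(states, seed=seed))
    return sample, trajectories


@dataclass(frozen=True)
class TrajectoryStats:
    """Population summaries of a set of trajectories.

    ``plateau`` is the copy number at the first silenced generation of each
    lineage (NaN for lineages that never silence), on the requested
    counting mode.
    """

    mean_copy_number: np.ndarray  # per generation, over all lineages
    silencing_generation: np.ndarray  # per lineage, NaN if never silenced
    plateau: np.ndarray  # per lineage, NaN if never silenced
    counting: str = "new_only"

    @property
    def mean_plateau(self) -> float:
        """Mean plateau copy number among lineages that silenced (NaN if none)."""
        vals = self.plateau[~np.isnan(self.plateau)]
        return float(vals.mean()) if vals.size else math.nan

    @property
    def fraction_silenced(self) -> float:
        return float(np.mean(~np.isnan(self.silencing_generation)))


def trajectory_stats(
    trajectories: Sequence[Trajectory], counting: str = "new_only"
) -> TrajectoryStats:
    """Per-generation mean copy number, silencing generation and plateau."""
    if len(trajectories) == 0:
        raise ValueError("trajectory_stats requires at least one trajectory")
    cn = np.stack([t.copy_numbers(counting) for t in trajectories])  # (L, G+1)
    sil = np.stack([[s.silenced for s in t.states] for t in trajectories])
    first_sil = np.where(sil.any(axis=1), sil.argmax(axis=1), -1)
    silencing_generation = np.where(first_sil >= 0, first_sil, np.nan)
    plateau = np.where(
        first_sil >= 0, cn[np.arange(len(trajectories)), first_sil], np.nan
    ).astype(float)
    return TrajectoryStats(
        mean_copy_number=cn.mean(axis=0),
        silencing_generation=silencing_generation,
        plateau=plateau,
        counting=counting,
    )
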