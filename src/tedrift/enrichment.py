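"""Randomization-based characterisation of TE insertion sites.

Given a set of insertion positions and a genome annotation, this module
answers where insertions land relative to genes (metagene hierarchy
5'UTR > 3'UTR > exon > intron > intergenic), chromatin states (1–9),
essential genes, parental-origin intervals, chromatin signal tracks
(meta-profiles over windows centred on insertion sites) and
well-positioned nucleosome dyads.

The null model for enrichment is positional: insertion positions are
re-drawn uniformly over the unmasked genome many times; observed category
counts are compared with the null distribution and summarised as a fold
change (observed / null mean) and an empirical p-value
p = (r + 1) / (N + 1), with r the number of null replicates at least as
extreme in the direction of the observed deviation.

All coordinates are 0-based, half-open (BED convention); GFF3 input is
converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

__all__ = [
    "GenomicInterval",
    "InsertionSite",
    "AnnotationSet",
    "SignalTrack",
    "EnrichmentReport",
    "METAGENE_CATEGORIES",
    "randomize_positions",
    "assign_metagene_category",
    "metagene_categories",
    "state_enrichment",
    "contingency_chi_square",
    "essential_gene_enrichment",
    "metaprofile",
    "dyad_distance_density",
    "interval_partition_counts",
    "sites_to_frame",
]

METAGENE_CATEGORIES = ("five_prime_utr", "three_prime_utr", "exon", "intron", "intergenic")
_PART_PRIORITY = ("five_prime_utr", "three_prime_utr", "exon", "intron")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError("strand must be '+', '-' or '.'")


@dataclass(frozen=True)
class InsertionSite:
    chrom: str
    position: int
    family: str = "TE"
    zygosity: str = "het"
    origin: str = "none"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be 'hom' or 'het'")
        if self.origin not in ("wt", "ddm1", "none"):
            raise ValueError("origin must be 'wt', 'ddm1' or 'none'")


def sites_to_frame(sites) -> pd.DataFrame:
    """Normalise a site collection (DataFrame or InsertionSite iterable) to a frame."""
    if isinstance(sites, pd.DataFrame):
        if not {"chrom", "pos"}.issubset(sites.columns):
            raise ValueError("site frame needs 'chrom' and 'pos' columns")
        return sites.reset_index(drop=True)
    rows = [(s.chrom, s.position, s.family, s.zygosity, s.origin) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "pos", "family", "zygosity", "origin"])


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms), np.asarray(me)


class _MembershipIndex:
    """Per-chromosome merged intervals supporting vectorised point membership."""

    def __init__(self, frame: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = _merge_intervals(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
            )

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = entry
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < ends[idx[ok]]
        return out


@dataclass
class SignalTrack:
    """Piecewise-constant per-bp signal (bedGraph semantics); gaps read as 0."""

    intervals: pd.DataFrame  # chrom, start, end, value
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "value"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"signal track needs columns {sorted(req)}")
        if not np.isfinite(self.intervals["value"]).all():
            raise ValueError("signal values must be finite")
        self.intervals = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._by_chrom = {
            str(c): (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64),
                     g["value"].to_numpy(np.float64))
            for c, g in self.intervals.groupby("chrom", sort=False)
        }

    def values_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        entry = self._by_chrom.get(chrom)
        out = np.zeros(pos.shape, dtype=np.float64)
        if entry is None:
            return out
        starts, ends, values = entry
        idx = np.searchsorted(starts, pos.ravel(), side="right") - 1
        ok = (idx >= 0) & (pos.ravel() < ends[np.clip(idx, 0, None)])
        flat = out.ravel()
        flat[ok] = values[idx[ok]]
        return flat.reshape(pos.shape)

    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray]) -> "SignalTrack":
        """Run-length encode dense per-bp arrays into a track."""
        rows = []
        for chrom, vals in arrays.items():
            vals = np.asarray(vals, dtype=np.float64)
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), float(vals[s])))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        return cls(frame, chrom_sizes={c: int(len(v)) for c, v in arrays.items()})


@dataclass
class AnnotationSet:
    """Genome annotation bundle used by every enrichment analysis.

    genes:       gene_id, chrom, start, end, strand, essential (bool)
    gene_parts:  gene_id, part (five_prime_utr/exon/intron/three_prime_utr), chrom, start, end
    states:      chrom, start, end, state (1..9), non-overlapping per bp
    dyads:       chrom, pos — nucleosome dyad midpoints
    mask:        chrom, start, end — regions excluded from the positional null
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    gene_parts: pd.DataFrame
    states: pd.DataFrame
    dyads: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        self.chrom_sizes = {str(k): int(v) for k, v in self.chrom_sizes.items()}
        self.genes = self.genes.reset_index(drop=True)
        if "essential" not in self.genes.columns:
            self.genes["essential"] = False
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene ID {dup!r}")
        for name in ("genes", "gene_parts", "states", "mask"):
            frame = getattr(self, name)
            if len(frame):
                bad = frame[(frame["start"] < 0) | (frame["start"] >= frame["end"])]
                if len(bad):
                    raise ValueError(f"{name}: invalid interval at row {bad.index[0]}")
                sizes = frame["chrom"].map(self.chrom_sizes)
                if sizes.isna().any():
                    raise ValueError(f"{name}: unknown chromosome "
                                     f"{frame.loc[sizes.isna(), 'chrom'].iloc[0]!r}")
                if (frame["end"] > sizes).any():
                    raise ValueError(f"{name}: interval beyond chromosome end")
        # chromatin states must not overlap
        st = self.states.sort_values(["chrom", "start"])
        for chrom, grp in st.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping chromatin states on {chrom}")
        # gene parts must lie within their gene
        if len(self.gene_parts):
            gmap = self.genes.set_index("gene_id")
            joined = self.gene_parts.join(gmap[["start", "end"]], on="gene_id", rsuffix="_gene")
            if ((joined["start"] < joined["start_gene"]) | (joined["end"] > joined["end_gene"])).any():
                raise ValueError("gene part outside its gene")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_sizes)

    @cached_property
    def _part_indexes(self) -> dict[str, _MembershipIndex]:
        return {
            part: _MembershipIndex(self.gene_parts[self.gene_parts["part"] == part])
            for part in _PART_PRIORITY
        }

    @cached_property
    def _gene_index(self) -> _MembershipIndex:
        return _MembershipIndex(self.genes)

    @cached_property
    def _state_lookup(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        out = {}
        for chrom, grp in self.states.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
            out[str(chrom)] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["state"].to_numpy(np.int64),
            )
        return out

    @cached_property
    def _dyad_lookup(self) -> dict[str, np.ndarray]:
        return {
            str(c): np.sort(g["pos"].to_numpy(np.int64))
            for c, g in self.dyads.groupby("chrom", sort=False)
        }

    @cached_property
    def unmasked(self) -> pd.DataFrame:
        """Complement of the mask within chromosome bounds (chrom, start, end)."""
        rows = []
        mask_by_chrom = {c: g for c, g in self.mask.groupby("chrom", sort=False)}
        for chrom in self.chroms:
            size = self.chrom_sizes[chrom]
            grp = mask_by_chrom.get(chrom)
            if grp is None or not len(grp):
                rows.append((chrom, 0, size))
                continue
            ms, me = _merge_intervals(grp["start"].to_numpy(np.int64),
                                      grp["end"].to_numpy(np.int64))
            cursor = 0
            for s, e in zip(ms, me):
                if s > cursor:
                    rows.append((chrom, cursor, int(s)))
                cursor = max(cursor, int(e))
            if cursor < size:
                rows.append((chrom, cursor, size))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def states_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Chromatin state (1..9) at each position; 0 where unassigned."""
        pos = np.asarray(pos, dtype=np.int64)
        entry = self._state_lookup.get(chrom)
        out = np.zeros(pos.shape, dtype=np.int64)
        if entry is None:
            return out
        starts, ends, labels = entry
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        out[ok] = labels[idx[ok]]
        return out


class RandomSites(NamedTuple):
    """Randomised positions: (reps, n) arrays of chromosome codes and positions."""

    chrom_idx: np.ndarray
    pos: np.ndarray
    chrom_names: tuple[str, ...]


def randomize_positions(
    n: int,
    annotation: AnnotationSet,
    reps: int,
    rng: np.random.Generator | int | None = None,
) -> RandomSites:
    """Draw ``reps`` sets of ``n`` positions uniform over the unmasked genome."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chroms = tuple(annotation.chroms)
    seg = annotation.unmasked
    if not len(seg) or (seg["end"] - seg["start"]).sum() == 0:
        raise ValueError("genome is fully masked: no unmasked bp to draw from")
    seg_chrom = seg["chrom"].map({c: i for i, c in enumerate(chroms)}).to_numpy(np.int64)
    seg_start = seg["start"].to_numpy(np.int64)
    lengths = (seg["end"] - seg["start"]).to_numpy(np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    g = rng.integers(0, total, size=(reps, n))
    si = np.searchsorted(offsets, g, side="right") - 1
    return RandomSites(seg_chrom[si], seg_start[si] + (g - offsets[si]), chroms)


# ---------------------------------------------------------------------------
# Metagene hierarchy
# ---------------------------------------------------------------------------


def metagene_categories(
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    annotation: AnnotationSet,
    chrom_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Vectorised metagene category codes (index into METAGENE_CATEGORIES).

    Overlaps are resolved by the stepwise hierarchy
    5'UTR > 3'UTR > exon > intron; positions inside a gene body that match
    no annotated part are classed as intron; everything else is intergenic.
    """
    chrom_names = tuple(chrom_names or annotation.chroms)
    chrom_idx = np.asarray(chrom_idx)
    pos = np.asarray(pos, dtype=np.int64)
    flat_ci, flat_pos = chrom_idx.ravel(), pos.ravel()
    codes = np.full(flat_pos.size, len(METAGENE_CATEGORIES) - 1, dtype=np.int64)  # intergenic
    intron_code = _PART_PRIORITY.index("intron")
    for ci, chrom in enumerate(chrom_names):
        sel = np.nonzero(flat_ci == ci)[0]
        if not sel.size:
            continue
        p = flat_pos[sel]
        assigned = np.zeros(p.size, dtype=bool)
        for rank, part in enumerate(_PART_PRIORITY):
            hit = annotation._part_indexes[part].contains(chrom, p) & ~assigned
            codes[sel[hit]] = rank
            assigned |= hit
        # gene-body positions with no part annotation default to intron
        in_gene = annotation._gene_index.contains(chrom, p) & ~assigned
        codes[sel[in_gene]] = intron_code
    return codes.reshape(pos.shape)


def _nearest_gene_distance(chrom: str, position: int, annotation: AnnotationSet):
    genes = annotation.genes[annotation.genes["chrom"] == chrom]
    if not len(genes):
        return None, None
    starts = genes["start"].to_numpy(np.int64)
    ends = genes["end"].to_numpy(np.int64)
    # bp gap to the gene: 0 if inside
    left = starts - position           # >0 when the site is left of the gene
    right = position - ends + 1        # >0 when the site is right of the gene
    gap = np.maximum(0, np.maximum(left, right))
    order = np.lexsort((starts, gap))
    i = order[0]
    gene = genes.iloc[i]
    d = int(gap[i])
    if d == 0:
        return gene, 0
    site_left_of_gene = position < starts[i]
    # Sign convention: negative upstream of the gene's TSS, positive past its
    # 3' end, respecting strand.
    if gene["strand"] == "-":
        signed = d if site_left_of_gene else -d
    else:
        signed = -d if site_left_of_gene else d
    return gene, signed


def assign_metagene_category(site, annotation: AnnotationSet):
    """Category of one insertion site plus, when intergenic, the signed
    distance to the nearest gene (negative upstream, positive downstream,
    by the gene's orientation)."""
    if isinstance(site, InsertionSite):
        chrom, position = site.chrom, site.position
    else:
        chrom, position = site
    if chrom not in annotation.chrom_sizes:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (0 <= position < annotation.chrom_sizes[chrom]):
        raise ValueError("position outside chromosome bounds")
    chroms = annotation.chroms
    code = metagene_categories(
        np.array([chroms.index(chrom)]), np.array([position]), annotation
    )[0]
    category = METAGENE_CATEGORIES[code]
    if category != "intergenic":
        return category, None
    _, signed = _nearest_gene_distance(chrom, position, annotation)
    return category, signed


# ---------------------------------------------------------------------------
# Randomization-based enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentReport:
    """Observed vs positional-null category counts.

    One row per category: observed count, null mean, fold (observed / null
    mean; NaN when the category is absent from both), empirical p
    (r + 1) / (N + 1) with r the count of null replicates at least as
    extreme on the analysis tail (over-representation by default).
    """

    table: pd.DataFrame
    reps: int

    def __post_init__(self) -> None:
        p = self.table["p_empirical"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("empirical p must lie in (0, 1]")


def _empirical_p(observed: np.ndarray, null_counts: np.ndarray, tail: str = "greater") -> np.ndarray:
    """Empirical p = (r+1)/(N+1), r counting null replicates at least as
    extreme as the observation.

    ``tail="greater"`` (the default, testing over-representation) counts
    replicates with a count >= observed; ``"less"`` tests depletion;
    ``"two-sided"`` counts replicates whose absolute deviation from the
    null mean is at least the observed one (conservative under ties).
    """
    reps = null_counts.shape[0]
    if tail == "greater":
        r = (null_counts >= observed).sum(axis=0)
    elif tail == "less":
        r = (null_counts <= observed).sum(axis=0)
    elif tail == "two-sided":
        mean = null_counts.mean(axis=0)
        r = (np.abs(null_counts - mean) >= np.abs(observed - mean)).sum(axis=0)
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    return (r + 1) / (reps + 1)


def state_enrichment(
    sites,
    annotation: AnnotationSet,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    tail: str = "greater",
) -> EnrichmentReport:
    """Observed vs randomised counts per chromatin state and metagene category."""
    frame = sites_to_frame(sites)
    if not len(frame):
        raise ValueError("no insertion sites supplied")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chroms = annotation.chroms
    cmap = {c: i for i, c in enumerate(chroms)}
    obs_ci = frame["chrom"].map(cmap).to_numpy(np.int64)
    obs_pos = frame["pos"].to_numpy(np.int64)
    n = len(frame)

    null = randomize_positions(n, annotation, reps, rng)

    state_labels = list(range(1, 10))
    rows = []

    def _state_counts(ci, pos):
        counts = np.zeros(10, dtype=np.int64)
        for i, chrom in enumerate(chroms):
            sel = ci == i
            if sel.any():
                counts += np.bincount(annotation.states_at(chrom, pos[sel]), minlength=10)
        return counts  # index 0 = unassigned

    obs_states = _state_counts(obs_ci, obs_pos)
    null_states = np.stack([_state_counts(null.chrom_idx[r], null.pos[r]) for r in range(reps)])

    obs_cat = np.bincount(metagene_categories(obs_ci, obs_pos, annotation),
                          minlength=len(METAGENE_CATEGORIES))
    null_cat_codes = metagene_categories(null.chrom_idx, null.pos, annotation)
    null_cats = np.stack([
        np.bincount(null_cat_codes[r], minlength=len(METAGENE_CATEGORIES))
        for r in range(reps)
    ])

    def _rows(kind, labels, obs, null_counts):
        p = _empirical_p(obs, null_counts, tail=tail)
        means = null_counts.mean(axis=0)
        for j, label in enumerate(labels):
            present = (obs[j] > 0) or (means[j] > 0)
            fold = obs[j] / means[j] if means[j] > 0 else (math.inf if obs[j] > 0 else math.nan)
            rows.append((kind, str(label), int(obs[j]), float(means[j]),
                         float(fold) if present else math.nan,
                         float(p[j]) if present else math.nan, present))

    _rows("state", state_labels, obs_states[1:], null_states[:, 1:])
    _rows("metagene", METAGENE_CATEGORIES, obs_cat, null_cats)

    table = pd.DataFrame(rows, columns=[
        "kind", "category", "observed", "null_mean", "fold", "p_empirical", "present",
    ])
    return EnrichmentReport(table=table, reps=reps)


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------


def contingency_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Raises on degenerate margins, naming the empty margin.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    row_names = ("row 0", "row 1")
    col_names = ("column 0", "column 1")
    for i, name in enumerate(row_names):
        if table[i].sum() == 0:
            raise ValueError(f"degenerate contingency table: {name} margin is zero")
    for j, name in enumerate(col_names):
        if table[:, j].sum() == 0:
            raise ValueError(f"degenerate contingency table: {name} margin is zero")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def essential_gene_enrichment(
    hit_genes: Iterable[str],
    all_target_genes: Iterable[str],
    annotation: AnnotationSet,
) -> tuple[float, int, float]:
    """Chi-square comparison of the essential-gene fraction among hit genes
    versus the remaining background genes.

    ``all_target_genes`` is the universe of candidate (protein-coding)
    genes; background = universe minus hits.
    """
    hits = set(hit_genes)
    universe = set(all_target_genes)
    if not hits or not universe:
        raise ValueError("gene sets must be non-empty")
    unknown = (hits | universe) - set(annotation.genes["gene_id"])
    if unknown:
        raise ValueError(f"unknown gene IDs: {sorted(unknown)[:3]}")
    essential = set(annotation.genes.loc[annotation.genes["essential"], "gene_id"])
    background = universe - hits
    table = np.array([
        [len(hits & essential), len(hits - essential)],
        [len(background & essential), len(background - essential)],
    ])
    return contingency_chi_square(table)


# ---------------------------------------------------------------------------
# Meta-profiles
# ---------------------------------------------------------------------------


def metaprofile(
    sites,
    track: SignalTrack,
    window: int = 4000,
    smoothing: tuple[str, float | None] = ("spline", None),
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-bp mean signal over windows centred on insertion sites.

    Offsets run from -window/2 to +window/2 inclusive.  Windows truncated
    at chromosome ends contribute only to the offsets they cover, so the
    mean at each offset is taken over the windows available there.
    Smoothing: ``("spline", lam)`` cubic smoothing spline (GCV-chosen
    penalty when lam is None) or ``("rolling", k)`` centred rolling mean.
    Returns a frame with columns offset, n, mean, smoothed.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even integer")
    frame = sites_to_frame(sites)
    sizes = chrom_sizes or track.chrom_sizes
    half = window // 2
    offsets = np.arange(-half, half + 1)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=np.int64)
    for chrom, grp in frame.groupby("chrom", sort=False):
        positions = grp["pos"].to_numpy(np.int64)
        size = None if sizes is None else sizes.get(str(chrom))
        if sizes is not None and size is None:
            continue  # unknown chromosome: nothing in bounds
        mat = positions[:, None] + offsets[None, :]
        valid = mat >= 0
        if size is not None:
            valid &= mat < size
        vals = track.values_at(str(chrom), np.where(valid, mat, 0))
        sums += np.where(valid, vals, 0.0).sum(axis=0)
        counts += valid.sum(axis=0)
    if counts.sum() == 0:
        raise ValueError("no site contributes any in-bounds window position")
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = counts > 0
    method, param = smoothing
    if method == "spline":
        spl = interpolate.make_smoothing_spline(
            offsets[ok].astype(float), mean[ok], lam=param
        )
        smoothed = np.where(ok, spl(offsets.astype(float)), np.nan)
    elif method == "rolling":
        k = int(param or 51)
        smoothed = (
            pd.Series(mean).rolling(k, center=True, min_periods=1).mean().to_numpy()
        )
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return pd.DataFrame({"offset": offsets, "n": counts, "mean": mean, "smoothed": smoothed})


# ---------------------------------------------------------------------------
# Nucleosome-dyad distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DyadDistanceResult:
    distances: np.ndarray
    n_excluded: int
    density: pd.DataFrame  # bin_mid, density
    mode: float
    bin_width: float
    signed: bool


def dyad_distance_density(
    sites,
    annotation: AnnotationSet,
    max_distance: int = 200,
    bin_width: float = 5.0,
    signed: bool = False,
) -> DyadDistanceResult:
    """Distance from each insertion site to the nearest nucleosome dyad.

    Distances are unsigned by default; ties between two equidistant dyads
    go to the lower-coordinate dyad.  Sites farther than ``max_distance``
    are excluded and counted.  The density is a histogram with bins of
    ``bin_width`` bp centred on multiples of the bin width, and the mode is
    the midpoint of the fullest bin (lowest midpoint on ties).
    """
    if not len(annotation.dyads):
        raise ValueError("annotation contains no nucleosome dyads")
    frame = sites_to_frame(sites)
    dist = np.empty(len(frame), dtype=np.float64)
    for chrom, grp in frame.groupby("chrom", sort=False):
        dyads = annotation._dyad_lookup.get(str(chrom))
        idx = grp.index.to_numpy()
        if dyads is None or dyads.size == 0:
            dist[idx] = np.inf
            continue
        pos = grp["pos"].to_numpy(np.int64)
        right = np.searchsorted(dyads, pos)
        left = np.clip(right - 1, 0, dyads.size - 1)
        right = np.clip(right, 0, dyads.size - 1)
        d_left = np.abs(pos - dyads[left])
        d_right = np.abs(dyads[right] - pos)
        use_left = d_left <= d_right  # tie -> lower-coordinate dyad
        nearest = dyads[np.where(use_left, left, right)]
        d = pos - nearest  # signed: positive when the site lies 3' of the dyad
        dist[idx] = d if signed else np.abs(d)
    keep = np.abs(dist) <= max_distance
    n_excluded = int((~keep).sum())
    kept = dist[keep]
    if kept.size == 0:
        raise ValueError("no site within max_distance of a dyad")
    lo = -max_distance if signed else 0.0
    edges = np.arange(lo - bin_width / 2, max_distance + bin_width, bin_width)
    hist, edges = np.histogram(kept, bins=edges, density=True)
    mids = (edges[:-1] + edges[1:]) / 2
    mode = float(mids[int(np.argmax(hist))])
    density = pd.DataFrame({"bin_mid": mids, "density": hist})
    return DyadDistanceResult(kept, n_excluded, density, mode, bin_width, signed)


# ---------------------------------------------------------------------------
# Parental-origin / pericentromere partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionCounts:
    """Sites cross-classified by parental origin and pericentromere/arm."""

    counts: pd.DataFrame  # index: origin, columns: region class

    def chi_square(self) -> tuple[float, int, float]:
        """Chi-square on the 2x2 origin x region table (shared engine)."""
        return contingency_chi_square(self.counts.to_numpy())


def interval_partition_counts(
    sites,
    parental_intervals: pd.DataFrame,
    pericentromeres: pd.DataFrame,
) -> PartitionCounts:
    """Count sites per parental origin (wt/ddm1) and region class (peri/arm).

    ``parental_intervals`` (chrom, start, end, origin) must partition each
    chromosome without overlap; every site must fall in exactly one
    interval.
    """
    frame = sites_to_frame(sites)
    pi = parental_intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, grp in pi.groupby("chrom", sort=False):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping parental intervals on {chrom}")
    peri_index = _MembershipIndex(pericentromeres)
    origins = np.empty(len(frame), dtype=object)
    regions = np.empty(len(frame), dtype=object)
    for chrom, grp in frame.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        sub = pi[pi["chrom"] == chrom]
        if not len(sub):
            raise ValueError(f"no parental intervals on chromosome {chrom}")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        labels = sub["origin"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        if (idx < 0).any() or (pos >= ends[np.clip(idx, 0, None)]).any():
            raise ValueError(f"site outside the parental partition on {chrom}")
        origins[grp.index] = labels[idx]
        regions[grp.index] = np.where(
            peri_index.contains(str(chrom), pos), "pericentromere", "arm"
        )
    counts = pd.crosstab(pd.Series(origins, name="origin"),
                         pd.Series(regions, name="region"))
    counts = counts.reindex(index=["wt", "ddm1"], columns=["pericentromere", "arm"],
                            fill_value=0)
    return PartitionCounts(counts=counts)
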