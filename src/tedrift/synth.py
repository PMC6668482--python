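"""Synthetic inputs with known ground truth for every pipeline stage.

Generates desk-scale toy genomes (annotation, chromatin states, nucleosome
dyads, masked pericentromeres, parental-origin mosaics), insertion-site
sets with planted biases (state targeting, metagene preference, dyad-offset
preference, parental pericentromere bias), per-bp signal tracks with
planted bumps, and model-drawn zygosity samples for parameter-recovery
tests.  Everything is deterministic given the seed and round-trips through
the io layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import (
    AnnotationSet,
    METAGENE_CATEGORIES,
    SignalTrack,
    metagene_categories,
)
from .simulate import TEModelParams, ZygositySample, simulate_population

__all__ = [
    "ToyGenomeSpec",
    "BiasSpec",
    "BumpSpec",
    "ToyGenome",
    "make_toy_genome",
    "plant_insertions",
    "make_signal_track",
    "make_observed_counts",
    "PRESETS",
]

# Default chromatin-state coverage fractions (of unmasked bp), states 1..9.
_DEFAULT_STATE_FRACTIONS = {
    1: 0.14, 2: 0.12, 3: 0.10, 4: 0.10, 5: 0.10,
    6: 0.08, 7: 0.08, 8: 0.09, 9: 0.09,
}


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Layout of a desk-scale toy genome.

    Defaults give two 200-kb chromosomes with ~80 genes, a central masked
    pericentromere core per chromosome, regularly spaced nucleosome dyads
    and chromatin states tiled in fixed-size windows at the requested
    coverage fractions.
    """

    chrom_lengths: tuple[int, ...] = (200_000, 200_000)
    n_genes: int = 80
    gene_length_mean: int = 1500
    gene_length_min: int = 600
    n_exons: int = 3
    utr_fraction: float = 0.1
    state_fractions: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_FRACTIONS)
    )
    state_window: int = 500
    essential_fraction: float = 0.2
    dyad_spacing: int = 180
    masked_fraction: float = 0.1
    pericentromere_fraction: float = 0.25
    parental_block_length: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        total = sum(self.state_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"state coverage fractions sum to {total:.3f} > 1")
        if any(not 1 <= s <= 9 for s in self.state_fractions):
            raise ValueError("chromatin states must be labelled 1..9")
        if not 0 <= self.masked_fraction < 1:
            raise ValueError("masked_fraction must lie in [0, 1)")
        if self.masked_fraction > self.pericentromere_fraction:
            raise ValueError("the mask must fit inside the pericentromere")
        if self.gene_length_min < 3 * (2 * self.n_exons + 1):
            raise ValueError("gene_length_min too small for the exon/intron layout")


@dataclass(frozen=True)
class ToyGenome:
    """A generated toy genome: annotation plus the extra interval sets."""

    annotation: AnnotationSet
    parental_intervals: pd.DataFrame  # chrom, start, end, origin
    pericentromeres: pd.DataFrame  # chrom, start, end
    spec: ToyGenomeSpec


def _gene_parts_for(gene_id, chrom, start, end, strand, n_exons, utr_fraction):
    """Tile a gene span completely: UTRs at the ends, exons/introns between."""
    length = end - start
    utr = max(1, int(round(utr_fraction * length)))
    body = length - 2 * utr
    n_chunks = 2 * n_exons - 1
    exon_bp = int(round(0.6 * body))
    intron_bp = body - exon_bp
    exon_sizes = [exon_bp // n_exons] * n_exons
    exon_sizes[0] += exon_bp - sum(exon_sizes)
    n_introns = n_exons - 1
    intron_sizes = [intron_bp // n_introns] * n_introns if n_introns else []
    if n_introns:
        intron_sizes[0] += intron_bp - sum(intron_sizes)
    sizes = [utr]
    kinds = ["five_prime_utr"]
    for i in range(n_chunks):
        if i % 2 == 0:
            sizes.append(exon_sizes[i // 2])
            kinds.append("exon")
        else:
            sizes.append(intron_sizes[i // 2])
            kinds.append("intron")
    sizes.append(utr)
    kinds.append("three_prime_utr")
    if strand == "-":
        kinds = ["three_prime_utr" if k == "five_prime_utr"
                 else "five_prime_utr" if k == "three_prime_utr" else k
                 for k in kinds]
    rows, cursor = [], start
    for kind, size in zip(kinds, sizes):
        rows.append((gene_id, kind, chrom, cursor, cursor + size))
        cursor += size
    assert cursor == end
    return rows


def make_toy_genome(spec: ToyGenomeSpec, outdir=None) -> ToyGenome:
    """Generate a toy genome; optionally write its files (GFF3, BEDs, lists).

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    files.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    sizes = dict(zip(chroms, spec.chrom_lengths))

    mask_rows, peri_rows = [], []
    for chrom, size in sizes.items():
        mid = size // 2
        peri_half = int(size * spec.pericentromere_fraction) // 2
        mask_half = int(size * spec.masked_fraction) // 2
        peri_rows.append((chrom, mid - peri_half, mid + peri_half))
        if mask_half:
            mask_rows.append((chrom, mid - mask_half, mid + mask_half))
    mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])
    peri = pd.DataFrame(peri_rows, columns=["chrom", "start", "end"])

    # Unmasked segments (genes and states live outside the masked core).
    segments = []
    for chrom, size in sizes.items():
        m = mask[mask["chrom"] == chrom]
        if len(m):
            segments.append((chrom, 0, int(m["start"].iloc[0])))
            segments.append((chrom, int(m["end"].iloc[0]), size))
        else:
            segments.append((chrom, 0, size))
    seg_lengths = np.array([e - s for _, s, e in segments], dtype=float)

    # Genes: apportion to segments by length, then place with random gaps.
    per_seg = np.floor(seg_lengths / seg_lengths.sum() * spec.n_genes).astype(int)
    per_seg[: spec.n_genes - per_seg.sum()] += 1
    gene_rows, part_rows = [], []
    gid = 0
    for (chrom, seg_start, seg_end), count in zip(segments, per_seg):
        if count == 0:
            continue
        lengths = np.maximum(
            spec.gene_length_min,
            rng.poisson(spec.gene_length_mean, size=count),
        )
        free = (seg_end - seg_start) - lengths.sum()
        if free < 0:
            raise ValueError("gene layout infeasible: segment too small for its genes")
        gaps = rng.multinomial(free, np.full(count + 1, 1 / (count + 1)))
        cursor = seg_start
        for j in range(count):
            cursor += int(gaps[j])
            gid += 1
            gene_id = f"G{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = cursor, cursor + int(lengths[j])
            gene_rows.append((gene_id, chrom, start, end, strand))
            part_rows.extend(
                _gene_parts_for(gene_id, chrom, start, end, strand,
                                spec.n_exons, spec.utr_fraction)
            )
            cursor = end
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    parts = pd.DataFrame(part_rows, columns=["gene_id", "part", "chrom", "start", "end"])
    genes["essential"] = rng.random(len(genes)) < spec.essential_fraction

    # Chromatin states: exact per-state window quotas shuffled over all
    # unmasked windows, so realised coverage matches the spec to <1 window.
    windows = []
    for chrom, seg_start, seg_end in segments:
        for w in range(seg_start, seg_end, spec.state_window):
            windows.append((chrom, w, min(w + spec.state_window, seg_end)))
    n_win = len(windows)
    labels = np.zeros(n_win, dtype=np.int64)
    quota_items = sorted(spec.state_fractions.items())
    cursor = 0
    for state, frac in quota_items:
        q = int(round(frac * n_win))
        labels[cursor:cursor + q] = state
        cursor += q
    rng.shuffle(labels)
    state_rows = [
        (chrom, s, e, int(lab))
        for (chrom, s, e), lab in zip(windows, labels)
        if lab > 0
    ]
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    # Nucleosome dyads: regular spacing with small jitter, genome-wide.
    dyad_rows = []
    for chrom, size in sizes.items():
        grid = np.arange(spec.dyad_spacing // 2, size, spec.dyad_spacing)
        jitter = rng.integers(-10, 11, size=grid.size)
        pos = np.clip(grid + jitter, 0, size - 1)
        dyad_rows.extend((chrom, int(p)) for p in np.sort(pos))
    dyads = pd.DataFrame(dyad_rows, columns=["chrom", "pos"])

    # Parental-origin mosaic: alternating wt/ddm1 blocks covering everything.
    parental_rows = []
    for chrom, size in sizes.items():
        origin = "wt" if rng.random() < 0.5 else "ddm1"
        for s in range(0, size, spec.parental_block_length):
            parental_rows.append((chrom, s, min(s + spec.parental_block_length, size), origin))
            origin = "ddm1" if origin == "wt" else "wt"
    parental = pd.DataFrame(parental_rows, columns=["chrom", "start", "end", "origin"])

    annotation = AnnotationSet(
        chrom_sizes=sizes, genes=genes, gene_parts=parts,
        states=states, dyads=dyads, mask=mask,
    )
    genome = ToyGenome(annotation=annotation, parental_intervals=parental,
                       pericentromeres=peri, spec=spec)
    if outdir is not None:
        _write_toy_genome(genome, Path(outdir))
    return genome


def _write_toy_genome(genome: ToyGenome, outdir: Path) -> None:
    from . import io  # local import: io depends on enrichment types only

    outdir.mkdir(parents=True, exist_ok=True)
    ann = genome.annotation
    io.write_gff3(ann.genes, ann.gene_parts, outdir / "genes.gff3")
    io.write_chrom_sizes(ann.chrom_sizes, outdir / "chrom.sizes")
    st = ann.states.rename(columns={"state": "name"})
    io.write_bed(st[["chrom", "start", "end", "name"]], outdir / "states.bed")
    dy = pd.DataFrame({
        "chrom": ann.dyads["chrom"], "start": ann.dyads["pos"],
        "end": ann.dyads["pos"] + 1,
    })
    io.write_bed(dy, outdir / "dyads.bed")
    if len(ann.mask):
        io.write_bed(ann.mask, outdir / "mask.bed")
    io.write_bed(genome.pericentromeres, outdir / "pericentromeres.bed")
    io.write_bed(genome.parental_intervals, outdir / "parental.bed")
    with open(outdir / "essential.txt", "w") as fh:
        for g in sorted(ann.genes.loc[ann.genes["essential"], "gene_id"]):
            fh.write(g + "\n")
    with open(outdir / "truth.json", "w") as fh:
        spec_dict = asdict(genome.spec)
        spec_dict["chrom_lengths"] = list(spec_dict["chrom_lengths"])
        json.dump(spec_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class BiasSpec:
    """Planted insertion preferences.

    Weights multiply the uniform per-bp sampling weight of the positional
    null; omitted classes default to weight 1.  ``dyad_offset`` plants a
    preference for landing at a fixed distance from the nearest nucleosome
    dyad: weight *= 1 + concentration * gauss(|d| - offset, width).
    ``peri_ddm1_multiplier`` up-weights pericentromeric bp of ddm1 parental
    origin.
    """

    state_weights: dict[int, float] = field(default_factory=dict)
    category_weights: dict[str, float] = field(default_factory=dict)
    dyad_offset: tuple[float, float, float] | None = None  # (offset, concentration, width)
    peri_ddm1_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.state_weights.values()):
            raise ValueError("state weights must be >= 0")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be >= 0")
        bad = set(self.category_weights) - set(METAGENE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown metagene categories: {sorted(bad)}")
        if self.peri_ddm1_multiplier < 0:
            raise ValueError("peri_ddm1_multiplier must be >= 0")


def plant_insertions(
    annotation: AnnotationSet,
    bias: BiasSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
    parental_intervals: pd.DataFrame | None = None,
    pericentromeres: pd.DataFrame | None = None,
    family: str = "TE",
) -> pd.DataFrame:
    """Draw ``n`` insertion sites over the unmasked genome with planted biases.

    Returns a site frame (chrom, pos, family, zygosity, origin) with
    ground-truth columns ``truth_state``, ``truth_category`` and
    ``truth_dyad_distance`` for downstream recovery tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chroms = annotation.chroms
    bp_chrom_idx, bp_pos = [], []
    for _, seg in annotation.unmasked.iterrows():
        span = np.arange(seg["start"], seg["end"], dtype=np.int64)
        bp_pos.append(span)
        bp_chrom_idx.append(np.full(span.size, chroms.index(seg["chrom"]), dtype=np.int64))
    bp_pos = np.concatenate(bp_pos)
    bp_chrom_idx = np.concatenate(bp_chrom_idx)

    weights = np.ones(bp_pos.size, dtype=np.float64)
    states = np.zeros(bp_pos.size, dtype=np.int64)
    cats = metagene_categories(bp_chrom_idx, bp_pos, annotation)
    dyad_dist = np.full(bp_pos.size, np.inf)
    for i, chrom in enumerate(chroms):
        sel = bp_chrom_idx == i
        states[sel] = annotation.states_at(chrom, bp_pos[sel])
        dyads = annotation._dyad_lookup.get(chrom)
        if dyads is not None and dyads.size:
            p = bp_pos[sel]
            right = np.clip(np.searchsorted(dyads, p), 0, dyads.size - 1)
            left = np.clip(np.searchsorted(dyads, p) - 1, 0, dyads.size - 1)
            dyad_dist[sel] = np.minimum(np.abs(p - dyads[left]), np.abs(dyads[right] - p))
    for state, w in bias.state_weights.items():
        weights[states == state] *= w
    for cat, w in bias.category_weights.items():
        weights[cats == METAGENE_CATEGORIES.index(cat)] *= w
    if bias.dyad_offset is not None:
        offset, conc, width = bias.dyad_offset
        finite = np.isfinite(dyad_dist)
        bump = np.zeros_like(weights)
        bump[finite] = np.exp(-0.5 * ((dyad_dist[finite] - offset) / width) ** 2)
        weights *= 1.0 + conc * bump
    if bias.peri_ddm1_multiplier != 1.0:
        if parental_intervals is None or pericentromeres is None:
            raise ValueError("origin bias requires parental_intervals and pericentromeres")
        from .enrichment import _MembershipIndex

        peri_idx = _MembershipIndex(pericentromeres)
        ddm1_idx = _MembershipIndex(
            parental_intervals[parental_intervals["origin"] == "ddm1"]
        )
        for i, chrom in enumerate(chroms):
            sel = bp_chrom_idx == i
            both = peri_idx.contains(chrom, bp_pos[sel]) & ddm1_idx.contains(chrom, bp_pos[sel])
            w = weights[sel]
            w[both] *= bias.peri_ddm1_multiplier
            weights[sel] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("bias spec yields all-zero sampling weights")

    draws = rng.choice(bp_pos.size, size=n, replace=True, p=weights / total)
    frame = pd.DataFrame({
        "chrom": [chroms[c] for c in bp_chrom_idx[draws]],
        "pos": bp_pos[draws],
        "family": family,
        # roughly two-thirds of fresh insertions are still heterozygous
        "zygosity": np.where(rng.random(n) < 2 / 3, "het", "hom"),
        "origin": "none",
        "truth_state": states[draws],
        "truth_category": [METAGENE_CATEGORIES[c] for c in cats[draws]],
        "truth_dyad_distance": dyad_dist[draws],
    })
    if parental_intervals is not None:
        pi = parental_intervals.sort_values(["chrom", "start"])
        for chrom, grp in frame.groupby("chrom", sort=False):
            sub = pi[pi["chrom"] == chrom]
            idx = np.searchsorted(sub["start"].to_numpy(), grp["pos"].to_numpy(),
                                  side="right") - 1
            frame.loc[grp.index, "origin"] = sub["origin"].to_numpy()[np.clip(idx, 0, None)]
    return frame


@dataclass(frozen=True)
class BumpSpec:
    """A planted signal feature: anchored bumps on a flat baseline."""

    anchor: str  # "tss", "dyad" or "positions"
    height: float = 1.0
    width: int = 100
    shape: str = "rect"  # rect | triangle | gauss
    positions: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.anchor not in ("tss", "dyad", "positions"):
            raise ValueError("anchor must be 'tss', 'dyad' or 'positions'")
        if self.shape not in ("rect", "triangle", "gauss"):
            raise ValueError("shape must be rect, triangle or gauss")
        if self.width < 1:
            raise ValueError("width must be >= 1")


def _bump_profile(shape: str, width: int, height: float) -> np.ndarray:
    x = np.arange(-width, width + 1, dtype=float)
    if shape == "rect":
        prof = np.full(x.size, height)
    elif shape == "triangle":
        prof = height * (1 - np.abs(x) / (width + 1))
    else:
        prof = height * np.exp(-0.5 * (x / (width / 2)) ** 2)
    return prof


def make_signal_track(
    annotation: AnnotationSet,
    bumps: tuple[BumpSpec, ...] = (),
    baseline: float = 1.0,
    decimals: int = 4,
) -> SignalTrack:
    """Per-bp signal: a flat baseline plus planted bumps at feature anchors.

    Deterministic (no noise) so tracks round-trip exactly through
    bedGraph; rounding keeps the text representation stable.
    """
    dense = {
        chrom: np.full(size, float(baseline))
        for chrom, size in annotation.chrom_sizes.items()
    }
    for bump in bumps:
        if bump.anchor == "tss":
            anchors = [
                (g.chrom, g.start if g.strand == "+" else g.end - 1)
                for g in annotation.genes.itertuples(index=False)
            ]
        elif bump.anchor == "dyad":
            anchors = list(annotation.dyads.itertuples(index=False, name=None))
        else:
            anchors = list(bump.positions)
        prof = _bump_profile(bump.shape, bump.width, bump.height)
        for chrom, center in anchors:
            arr = dense[str(chrom)]
            lo = int(center) - bump.width
            hi = int(center) + bump.width + 1
            plo, phi = max(lo, 0), min(hi, arr.size)
            arr[plo:phi] += prof[plo - lo: prof.size - (hi - phi)]
    dense = {c: np.round(v, decimals) for c, v in dense.items()}
    return SignalTrack.from_dense(dense)


def make_observed_counts(
    params: TEModelParams,
    n_lines: int,
    rng: np.random.Generator | int | None = None,
    outdir=None,
) -> tuple[ZygositySample, dict]:
    """Draw an observation-like zygosity sample from the model, with a truth
    sidecar recording the generating parameters."""
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    sample, _ = simulate_population(params, n_lines, rng, keep_trajectories=False)
    truth = {
        "variant": params.variant,
        "K": params.K,
        "E": params.E,
        "l": None if math.isinf(params.l) else int(params.l),
        "n_generations": params.n_generations,
        "donor_zygosity_at_start": params.donor_zygosity_at_start,
        "counting": params.counting,
        "n_lines": n_lines,
        "seed": seed,
    }
    if outdir is not None:
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_counts_tsv(sample, outdir / "observed_counts.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return sample, truth


# Qualitative regimes mirroring the three studied TE families: a
# copia-like retroelement (no excision, copy-number silencing around 40 new
# copies), a vandal-like DNA transposon (rare excision) and an enspm-like
# DNA transposon (frequent excision).
PRESETS = {
    "copia-like": TEModelParams(variant="transposon", K=0.25, E=0.0, l=40),
    "vandal-like": TEModelParams(variant="transposon", K=0.4, E=0.05, l=math.inf),
    "enspm-like": TEModelParams(variant="transposon", K=0.8, E=0.92, l=math.inf),
}
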