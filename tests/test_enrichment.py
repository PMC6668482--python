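"""Tests of the randomization-based insertion-site enrichment analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tedrift import (
    AnnotationSet,
    BiasSpec,
    InsertionSite,
    SignalTrack,
    assign_metagene_category,
    contingency_chi_square,
    dyad_distance_density,
    essential_gene_enrichment,
    interval_partition_counts,
    metagene_categories,
    metaprofile,
    plant_insertions,
    randomize_positions,
    state_enrichment,
)
from tedrift.enrichment import METAGENE_CATEGORIES

from conftest import sites_frame


# ---------------------------------------------------------------------- null


def test_randomized_positions_respect_mask(annotation):
    rng = np.random.default_rng(0)
    draws = randomize_positions(50, annotation, reps=200, rng=rng)
    mask = annotation.mask
    for r in range(draws.pos.shape[0]):
        for ci, pos in zip(draws.chrom_idx[r], draws.pos[r]):
            chrom = draws.chrom_names[ci]
            rows = mask[mask["chrom"] == chrom]
            assert not ((rows["start"] <= pos) & (pos < rows["end"])).any()
            assert 0 <= pos < annotation.chrom_sizes[chrom]


def test_randomized_positions_single_free_bp():
    ann = AnnotationSet(
        chrom_sizes={"chr1": 10},
        genes=pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"]),
        gene_parts=pd.DataFrame(columns=["gene_id", "part", "chrom", "start", "end"]),
        states=pd.DataFrame(columns=["chrom", "start", "end", "state"]),
        dyads=pd.DataFrame(columns=["chrom", "pos"]),
        mask=pd.DataFrame([("chr1", 0, 4), ("chr1", 5, 10)],
                          columns=["chrom", "start", "end"]),
    )
    draws = randomize_positions(3, ann, reps=20, rng=1)
    assert (draws.pos == 4).all()
    ann_full = AnnotationSet(
        chrom_sizes=ann.chrom_sizes, genes=ann.genes, gene_parts=ann.gene_parts,
        states=ann.states, dyads=ann.dyads,
        mask=pd.DataFrame([("chr1", 0, 10)], columns=["chrom", "start", "end"]),
    )
    with pytest.raises(ValueError, match="masked"):
        randomize_positions(1, ann_full, reps=1, rng=1)


def test_randomized_positions_uniform_over_bins(annotation):
    """Per-bin frequencies over 10 equal unmasked bins within 3*SE of uniform."""
    rng = np.random.default_rng(7)
    n, reps = 1000, 100
    draws = randomize_positions(n, annotation, reps=reps, rng=rng)
    # map every draw to its rank within the concatenated unmasked space
    seg = annotation.unmasked
    chrom_code = {c: i for i, c in enumerate(draws.chrom_names)}
    seg_offsets, cum = {}, 0
    for row in seg.itertuples(index=False):
        seg_offsets[(chrom_code[row.chrom], row.start, row.end)] = cum
        cum += row.end - row.start
    ranks = np.empty(draws.pos.size, dtype=np.int64)
    flat_ci, flat_pos = draws.chrom_idx.ravel(), draws.pos.ravel()
    for (ci, s, e), off in seg_offsets.items():
        sel = (flat_ci == ci) & (flat_pos >= s) & (flat_pos < e)
        ranks[sel] = off + flat_pos[sel] - s
    bins = np.floor(ranks / cum * 10).astype(int)
    counts = np.bincount(bins, minlength=10)
    total = n * reps
    p = 1 / 10
    se = math.sqrt(total * p * (1 - p))
    assert np.abs(counts - total * p).max() < 3 * se


# ------------------------------------------------------------------ metagene


def test_metagene_hierarchy_prefers_utr_over_exon(mini_annotation):
    category, signed = assign_metagene_category(("chr1", 3050), mini_annotation)
    assert category == "five_prime_utr" and signed is None
    assert assign_metagene_category(("chr1", 3200), mini_annotation)[0] == "exon"
    assert assign_metagene_category(("chr1", 3450), mini_annotation)[0] == "intron"
    assert assign_metagene_category(("chr1", 7050), mini_annotation)[0] == "three_prime_utr"


def test_metagene_signed_distance_convention(mini_annotation):
    """Downstream of a + gene is positive; upstream of a - gene is negative."""
    category, signed = assign_metagene_category(("chr1", 4499), mini_annotation)
    assert category == "intergenic" and signed == 500  # 500 bp past Gp's 3' end
    category, signed = assign_metagene_category(("chr1", 8499), mini_annotation)
    assert category == "intergenic" and signed == -500  # 500 bp 5' of Gm
    category, signed = assign_metagene_category(("chr1", 2501), mini_annotation)
    assert category == "intergenic" and signed == -499  # upstream of + strand Gp


def test_metagene_categories_are_exhaustive(annotation):
    rng = np.random.default_rng(3)
    draws = randomize_positions(500, annotation, reps=1, rng=rng)
    codes = metagene_categories(draws.chrom_idx[0], draws.pos[0], annotation)
    counts = np.bincount(codes, minlength=len(METAGENE_CATEGORIES))
    assert counts.sum() == 500


# ---------------------------------------------------------------- enrichment


def test_state_enrichment_self_consistency(annotation):
    """Sites that ARE a null draw show fold ~ 1 in well-covered states."""
    rng = np.random.default_rng(5)
    draws = randomize_positions(800, annotation, reps=1, rng=rng)
    frame = sites_frame([draws.chrom_names[c] for c in draws.chrom_idx[0]], draws.pos[0])
    table = state_enrichment(frame, annotation, reps=400, rng=rng).table
    states = table[table["kind"] == "state"]
    assert states["observed"].sum() <= 800
    covered = states[states["null_mean"] > 20]
    assert ((covered["fold"] > 0.7) & (covered["fold"] < 1.3)).all()


def test_state_enrichment_recovers_planted_bias(annotation, toy_genome):
    """Weight w on a state of genomic fraction f gives fold w/(w f + 1 - f)."""
    rng = np.random.default_rng(9)
    w = 9.0
    sites = plant_insertions(annotation, BiasSpec(state_weights={5: w}), 400, rng)
    table = state_enrichment(sites, annotation, reps=1000, rng=rng).table
    row = table[(table["kind"] == "state") & (table["category"] == "5")].iloc[0]
    un = (annotation.unmasked["end"] - annotation.unmasked["start"]).sum()
    s5 = annotation.states[annotation.states["state"] == 5]
    f = (s5["end"] - s5["start"]).sum() / un
    expected_fold = w / (w * f + (1 - f))
    assert row["fold"] == pytest.approx(expected_fold, rel=0.15)
    assert row["p_empirical"] <= 0.01


def test_state_enrichment_absent_state_reported_absent(mini_annotation):
    frame = sites_frame(["chr1", "chr1"], [600, 700])
    table = state_enrichment(frame, mini_annotation, reps=50, rng=2).table
    row9 = table[(table["kind"] == "state") & (table["category"] == "9")].iloc[0]
    assert not row9["present"]
    assert math.isnan(row9["fold"]) and math.isnan(row9["p_empirical"])


def test_null_p_values_are_uniform(annotation):
    """Sites drawn from the positional null give ~uniform empirical p."""
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(200):
        draw = randomize_positions(60, annotation, reps=1, rng=rng)
        frame = sites_frame([draw.chrom_names[c] for c in draw.chrom_idx[0]], draw.pos[0])
        table = state_enrichment(frame, annotation, reps=99, rng=rng).table
        ps.append(float(table[(table["kind"] == "state")
                              & (table["category"] == "1")]["p_empirical"].iloc[0]))
    ks = stats.kstest(np.array(ps), "uniform")
    assert ks.statistic < 1.628 / math.sqrt(len(ps))  # alpha = 0.01


def test_fold_invariant_under_genome_and_site_doubling(mini_annotation):
    """Doubling every state's extent and the site set leaves folds unchanged."""
    ann1 = mini_annotation
    doubled = {
        "chrom_sizes": {"chr1": 10_000, "chr2": 10_000},
        "genes": ann1.genes,
        "gene_parts": ann1.gene_parts,
        "states": pd.concat([ann1.states, ann1.states.assign(chrom="chr2")],
                            ignore_index=True),
        "dyads": ann1.dyads,
        "mask": pd.concat([ann1.mask, ann1.mask.assign(chrom="chr2")],
                          ignore_index=True),
    }
    ann2 = AnnotationSet(**doubled)
    pos = [1100, 1500, 1900, 2500, 6000, 9000]
    f1 = sites_frame(["chr1"] * len(pos), pos)
    f2 = pd.concat([f1, f1.assign(chrom="chr2")], ignore_index=True)
    t1 = state_enrichment(f1, ann1, reps=3000, rng=11).table
    t2 = state_enrichment(f2, ann2, reps=3000, rng=11).table
    r1 = t1[(t1["kind"] == "state") & (t1["category"] == "5")].iloc[0]
    r2 = t2[(t2["kind"] == "state") & (t2["category"] == "5")].iloc[0]
    assert r2["observed"] == 2 * r1["observed"]
    assert r2["fold"] == pytest.approx(r1["fold"], rel=0.1)


# --------------------------------------------------------------- chi-square


def test_chi_square_matches_closed_form_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(200):
        table = rng.integers(1, 100, size=(2, 2)).astype(float)
        stat, dof, p = contingency_chi_square(table)
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum @ colsum / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle)
        assert dof == 1
        # statistic symmetric under swapping group labels (rows)
        assert contingency_chi_square(table[::-1])[0] == pytest.approx(oracle)


def test_chi_square_hand_computed_table():
    # N (ad - bc)^2 / (r1 r2 c1 c2) = 200 * (10*70 - 90*30)^2 / (100*100*40*160)
    stat, dof, p = contingency_chi_square([[10, 90], [30, 70]])
    assert stat == pytest.approx(12.5)
    assert p == pytest.approx(stats.chi2.sf(12.5, 1))


def test_chi_square_degenerate_margin_names_the_margin():
    with pytest.raises(ValueError, match="column 1"):
        contingency_chi_square([[5, 0], [7, 0]])
    with pytest.raises(ValueError, match="row 0"):
        contingency_chi_square([[0, 0], [7, 3]])


def test_essential_gene_enrichment_null_case(mini_annotation):
    """Equal essential fractions in hits and background give stat 0, p 1."""
    genes = pd.DataFrame(
        [
            (f"G{i}", "chr1", 100 * i, 100 * i + 50, "+", i % 2 == 0)
            for i in range(1, 9)
        ],
        columns=["gene_id", "chrom", "start", "end", "strand", "essential"],
    )
    ann = AnnotationSet(
        chrom_sizes={"chr1": 10_000}, genes=genes,
        gene_parts=mini_annotation.gene_parts.iloc[:0],
        states=mini_annotation.states.iloc[:0],
        dyads=mini_annotation.dyads.iloc[:0], mask=mini_annotation.mask.iloc[:0],
    )
    hits = {"G2", "G3"}  # one essential, one not
    stat, dof, p = essential_gene_enrichment(hits, {f"G{i}" for i in range(1, 9)}, ann)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        essential_gene_enrichment(set(), {"G1"}, ann)


# -------------------------------------------------------------- metaprofile


def _flat_track(value, size=10_000):
    return SignalTrack(
        pd.DataFrame([("chr1", 0, size, value)],
                     columns=["chrom", "start", "end", "value"]),
        chrom_sizes={"chr1": size},
    )


def test_metaprofile_constant_track():
    frame = sites_frame(["chr1"] * 3, [3000, 5000, 7000])
    prof = metaprofile(frame, _flat_track(7.0), window=400)
    assert (prof["mean"] == 7.0).all()
    assert np.allclose(prof["smoothed"], 7.0, atol=1e-6)
    assert prof["offset"].iloc[0] == -200 and prof["offset"].iloc[-1] == 200


def test_metaprofile_reproduces_rectangular_bump():
    track = SignalTrack(
        pd.DataFrame(
            [("chr1", 0, 4950, 0.0), ("chr1", 4950, 5051, 3.0), ("chr1", 5051, 10_000, 0.0)],
            columns=["chrom", "start", "end", "value"],
        ),
        chrom_sizes={"chr1": 10_000},
    )
    prof = metaprofile(sites_frame(["chr1"], [5000]), track, window=400,
                       smoothing=("rolling", 1))
    inside = (prof["offset"] >= -50) & (prof["offset"] <= 50)
    assert (prof.loc[inside, "mean"] == 3.0).all()
    assert (prof.loc[~inside, "mean"] == 0.0).all()


def test_metaprofile_truncated_windows_use_per_offset_counts():
    prof = metaprofile(sites_frame(["chr1"], [100]), _flat_track(2.0), window=400)
    # a site 100 bp from the chromosome start covers offsets >= -100 only
    assert prof.loc[prof["offset"] == -100, "n"].iloc[0] == 1
    assert prof.loc[prof["offset"] == -100, "mean"].iloc[0] == 2.0
    assert (prof.loc[prof["offset"] < -100, "n"] == 0).all()
    assert prof.loc[prof["offset"] < -100, "mean"].isna().all()
    with pytest.raises(ValueError):
        metaprofile(sites_frame(["chrX"], [100]), _flat_track(2.0), window=400)


def test_metaprofile_recovers_planted_peak(annotation):
    """Sites centred on planted triangular bumps peak at offset 0 +- 10 bp."""
    from tedrift import BumpSpec, make_signal_track

    rng = np.random.default_rng(21)
    positions = randomize_positions(500, annotation, reps=1, rng=rng)
    anchors = tuple(
        (positions.chrom_names[c], int(p))
        for c, p in zip(positions.chrom_idx[0], positions.pos[0])
    )
    track = make_signal_track(
        annotation,
        bumps=(BumpSpec(anchor="positions", positions=anchors, height=3.0,
                        width=150, shape="triangle"),),
    )
    frame = sites_frame([a[0] for a in anchors], [a[1] for a in anchors])
    prof = metaprofile(frame, track, window=4000,
                       chrom_sizes=annotation.chrom_sizes)
    peak = prof.loc[prof["smoothed"].idxmax(), "offset"]
    assert abs(peak) <= 10


# ------------------------------------------------------------------- dyads


def test_dyad_distances_zero_when_sites_on_dyads(annotation):
    dy = annotation.dyads.iloc[:200]
    frame = sites_frame(dy["chrom"], dy["pos"])
    result = dyad_distance_density(frame, annotation, max_distance=100)
    assert (result.distances == 0).all()
    assert result.mode == 0.0


def test_dyad_nearest_tie_goes_to_lower_coordinate(mini_annotation):
    result = dyad_distance_density(
        sites_frame(["chr1"], [150]), mini_annotation, max_distance=100, signed=True
    )
    assert result.distances[0] == 50  # site minus the lower dyad (100)


def test_dyad_offset_recovery_and_exclusion(annotation):
    """Sites planted at dyad +-55 bp give an unsigned mode of 55."""
    rng = np.random.default_rng(33)
    dy = annotation.dyads.sample(400, random_state=1)
    offsets = np.where(rng.random(len(dy)) < 0.5, 55, -55)
    pos = np.clip(dy["pos"].to_numpy() + offsets, 0, None)
    frame = sites_frame(dy["chrom"], pos)
    result = dyad_distance_density(frame, annotation, max_distance=120, bin_width=5.0)
    assert abs(result.mode - 55) <= result.bin_width
    far = sites_frame(dy["chrom"].iloc[:5], dy["pos"].iloc[:5])
    res2 = dyad_distance_density(far, annotation, max_distance=0)
    assert res2.distances.size + res2.n_excluded == 5


# --------------------------------------------------- parental-origin counts


def test_interval_partition_counts_basic(toy_genome):
    ann = toy_genome.annotation
    wt = toy_genome.parental_intervals.query("origin == 'wt'")
    peri = toy_genome.pericentromeres
    # pick wt positions on chromosome arms only
    rows = []
    for r in wt.itertuples(index=False):
        mid = (r.start + r.end) // 2
        in_peri = ((peri["chrom"] == r.chrom) & (peri["start"] <= mid)
                   & (mid < peri["end"])).any()
        if not in_peri:
            rows.append((r.chrom, mid))
    frame = sites_frame([c for c, _ in rows], [p for _, p in rows])
    counts = interval_partition_counts(frame, toy_genome.parental_intervals, peri).counts
    assert counts.loc["wt", "arm"] == len(rows)
    assert counts.to_numpy().sum() == len(rows)
    with pytest.raises(ValueError, match="margin"):
        interval_partition_counts(frame, toy_genome.parental_intervals, peri).chi_square()


def test_interval_partition_rejects_overlaps(toy_genome):
    bad = toy_genome.parental_intervals.copy()
    bad.loc[1, "start"] = bad.loc[0, "start"]
    with pytest.raises(ValueError, match="overlap"):
        interval_partition_counts(
            sites_frame(["chr1"], [10]), bad, toy_genome.pericentromeres
        )


def test_planted_pericentromere_origin_bias_is_detected(toy_genome):
    ann = toy_genome.annotation
    rng = np.random.default_rng(55)
    sites = plant_insertions(
        ann, BiasSpec(peri_ddm1_multiplier=8.0), 600, rng,
        parental_intervals=toy_genome.parental_intervals,
        pericentromeres=toy_genome.pericentromeres,
    )
    result = interval_partition_counts(sites, toy_genome.parental_intervals,
                                       toy_genome.pericentromeres)
    stat, dof, p = result.chi_square()
    peri_frac = result.counts["pericentromere"] / result.counts.sum(axis=1)
    assert peri_frac["ddm1"] > peri_frac["wt"]
    assert p <= 0.01


def test_insertion_site_objects_are_accepted(mini_annotation):
    sites = [InsertionSite("chr1", 3050), InsertionSite("chr1", 6000)]
    table = state_enrichment(sites, mini_annotation, reps=20, rng=1).table
    assert table["observed"].max() >= 0
    category, _ = assign_metagene_category(InsertionSite("chr1", 3050), mini_annotation)
    assert category == "five_prime_utr"
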