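"""Individual identification: distances, clustering, sex resolution, histories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nigcmr import genotyping, identity
from nigcmr.simulate import corrupt_to_replicates, histories_from_truth

LOCI = ["L1", "L2", "L3", "L4", "L5", "L6", "L7"]


def geno(pairs, **pattern):
    g = dict(zip(LOCI, pairs))
    g.update(pattern)
    return g


BASE = [(1, 2), (3, 3), (5, 6), (7, 8), (9, 9), (11, 12), (13, 14)]


@pytest.mark.parametrize(
    "g2, expected",
    [
        (BASE, (0, 7)),                                       # identical
        ([(1, 3)] + BASE[1:], (1, 7)),                        # A/B vs A/C
        ([(3, 4)] + BASE[1:], (2, 7)),                        # A/B vs C/D
        ([(1, 1)] + BASE[1:], (1, 7)),                        # A/B vs A/A
        ([None] + BASE[1:], (0, 6)),                          # missing skipped
        ([None] * 7, (0, 0)),                                 # nothing comparable
    ],
)
def test_genotype_distance_pairs(g2, expected):
    assert identity.genotype_distance(geno(BASE), geno(g2), LOCI) == expected


pair_st = st.one_of(
    st.none(),
    st.tuples(st.integers(1, 4), st.integers(1, 4)).map(lambda p: tuple(sorted(p))),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(pair_st, min_size=7, max_size=7),
    st.lists(pair_st, min_size=7, max_size=7),
)
def test_genotype_distance_is_a_symmetric_bounded_count(pairs1, pairs2):
    g1, g2 = geno(pairs1), geno(pairs2)
    mism, compared = identity.genotype_distance(g1, g2, LOCI)
    assert identity.genotype_distance(g2, g1, LOCI) == (mism, compared)
    assert 0 <= mism <= 2 * compared
    assert compared <= len(LOCI)
    assert identity.genotype_distance(g1, g1, LOCI)[0] == 0


def test_pattern_locus_contributes_two_mismatches():
    g1 = geno(BASE, P1="x")
    g2 = geno(BASE, P1="y")
    assert identity.genotype_distance(g1, g2, LOCI, ["P1"]) == (2, 8)
    g3 = geno(BASE, P1="x")
    assert identity.genotype_distance(g1, g3, LOCI, ["P1"]) == (0, 8)


def _consensus_frame(rows):
    recs = []
    for sample_id, pairs, sex, session, day in rows:
        rec = {
            "sample_id": sample_id, "session": session, "day": day,
            "method": "systematic", "accepted": True, "sex": sex,
            "n_scored": 7,
        }
        for locus, pair in zip(LOCI, pairs):
            rec[locus] = "" if pair is None else f"{pair[0]}/{pair[1]}"
        recs.append(rec)
    return pd.DataFrame(recs)


OTHER = [(2, 2), (3, 4), (5, 5), (7, 7), (9, 10), (11, 11), (15, 16)]


def test_identical_genotypes_form_one_individual():
    df = _consensus_frame(
        [("s1", BASE, "F", "A", 1), ("s2", BASE, "F", "A", 2)]
    )
    inds = identity.cluster_individuals(df, LOCI)
    assert len(inds) == 1
    assert inds[0].n_samples == 2
    assert inds[0].genotype["L1"] == (1, 2)


def test_three_mismatches_split_individuals():
    far = [(1, 3), (4, 4)] + BASE[2:]   # 1 + 2 = 3 mismatched alleles
    df = _consensus_frame([("s1", BASE, "F", "A", 1), ("s2", far, "F", "A", 2)])
    assert len(identity.cluster_individuals(df, LOCI)) == 2
    near = [(1, 3), (3, 4)] + BASE[2:]  # 1 + 1 = 2 -> same individual
    df = _consensus_frame([("s1", BASE, "F", "A", 1), ("s2", near, "F", "A", 2)])
    assert len(identity.cluster_individuals(df, LOCI)) == 1


def test_sparse_genotypes_do_not_merge():
    sparse = BASE[:4] + [None, None, None]  # 4 comparable loci < minimum 5
    df = _consensus_frame([("s1", BASE, "F", "A", 1), ("s2", sparse, "F", "A", 2)])
    assert len(identity.cluster_individuals(df, LOCI)) == 2


def test_false_female_reclassification():
    df = _consensus_frame(
        [("s1", BASE, "M", "A", 1), ("s2", BASE, "F", "A", 2)]
    )
    inds = identity.cluster_individuals(df, LOCI)
    assert len(inds) == 1
    assert inds[0].sex == "M"
    assert inds[0].false_female_members == ["s2"]

    df = _consensus_frame(
        [("s1", BASE, "F", "A", 1), ("s2", BASE, "F", "A", 2)]
    )
    inds = identity.cluster_individuals(df, LOCI)
    assert inds[0].sex == "F" and inds[0].false_female_members == []


def test_cluster_count_nonincreasing_in_threshold():
    rows = [
        ("s1", BASE, "F", "A", 1),
        ("s2", [(1, 3)] + BASE[1:], "F", "A", 2),
        ("s3", OTHER, "F", "A", 3),
        ("s4", [(2, 3), (3, 4)] + BASE[2:], "F", "A", 4),
    ]
    df = _consensus_frame(rows)
    counts = [
        len(identity.cluster_individuals(df, LOCI, max_mismatch=m))
        for m in (0, 1, 2, 4, 6)
    ]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] == 4  # exact-genotype grouping


def test_clustering_invariant_to_row_order(default_sim):
    cfg, truth, replicates, samples = default_sim
    pats = samples[["sample_id"] + cfg.pattern_loci]
    cons = genotyping.consensus_table(replicates, loci=cfg.loci, patterns=pats)
    ref = identity.cluster_individuals(cons, cfg.loci, cfg.pattern_loci)
    shuffled = cons.sample(frac=1.0, random_state=42).reset_index(drop=True)
    alt = identity.cluster_individuals(shuffled, cfg.loci, cfg.pattern_loci)
    part_ref = sorted(frozenset(i.members.sample_id) for i in ref)
    part_alt = sorted(frozenset(i.members.sample_id) for i in alt)
    assert part_ref == part_alt


def test_error_free_pipeline_recovers_truth_exactly(clean_sim):
    """On error-free data the clusters, sexes and capture histories equal the
    generator's ground truth."""
    cfg, truth, replicates, samples = clean_sim
    pats = samples[["sample_id"] + cfg.pattern_loci]
    cons = genotyping.consensus_table(replicates, loci=cfg.loci, patterns=pats)
    inds = identity.cluster_individuals(cons, cfg.loci, cfg.pattern_loci)

    captured = truth.captured_individuals()
    assert len(inds) == len(captured) == 50

    src = dict(zip(samples.sample_id, samples.source_individual))
    for ind in inds:
        sources = {src[s] for s in ind.members.sample_id}
        assert len(sources) == 1  # purity
        i = sources.pop()
        assert ind.sex == truth.sexes[i]
        assert all(
            ind.genotype[locus] == truth.genotypes[i][locus] for locus in cfg.loci
        )

    cal = identity.calendar_from_samples(samples)
    chs = identity.build_histories(inds, cal)
    ref = histories_from_truth(truth)
    assert chs.total_detections() == ref.total_detections()
    got = {frozenset(map(tuple, np.argwhere(chs.detections[i]))) for i in range(chs.n_genotypes)}
    want = {frozenset(map(tuple, np.argwhere(ref.detections[i]))) for i in range(ref.n_genotypes)}
    assert got == want


def test_build_histories_day_pattern_and_conservation():
    rows = [
        ("s1", BASE, "F", "P01-spring", 2),
        ("s2", BASE, "F", "P01-spring", 5),
        ("s3", OTHER, "M", "P02-fall", 1),
    ]
    df = _consensus_frame(rows)
    inds = identity.cluster_individuals(df, LOCI)
    cal = pd.DataFrame(
        {
            "session": ["P01-spring", "P02-fall"],
            "pso": [1, 2],
            "season": ["spring", "fall"],
            "n_days": [5, 5],
        }
    )
    chs = identity.build_histories(inds, cal)
    ind_f = [i for i in range(chs.n_genotypes) if chs.groups[i] == "F"][0]
    assert chs.detections[ind_f, 0].tolist() == [False, True, False, False, True]
    assert chs.detections[ind_f, 1].sum() == 0
    assert chs.total_detections() == 3  # one per (individual, PSO, SSO) sampled


def test_systematic_only_filter_drops_opportunistic_detections():
    df = _consensus_frame(
        [("s1", BASE, "F", "P01-spring", 1), ("s2", BASE, "F", "P01-spring", 3)]
    )
    df.loc[df.sample_id == "s2", "method"] = "opportunistic"
    inds = identity.cluster_individuals(df, LOCI)
    cal = pd.DataFrame(
        {"session": ["P01-spring"], "pso": [1], "season": ["spring"], "n_days": [5]}
    )
    full = identity.build_histories(inds, cal)
    syst = identity.build_histories(inds, cal, systematic_only=True)
    assert full.total_detections() == 2
    assert syst.total_detections() == 1


def test_unknown_session_raises():
    df = _consensus_frame([("s1", BASE, "F", "Pxx", 1)])
    inds = identity.cluster_individuals(df, LOCI)
    cal = pd.DataFrame(
        {"session": ["P01-spring"], "pso": [1], "season": ["spring"], "n_days": [5]}
    )
    with pytest.raises(ValueError):
        identity.build_histories(inds, cal)


def test_false_females_on_simulated_sex_marker_dropout():
    """With only sex-marker dropout, false females are exactly the male
    samples whose replicates all failed, inside clusters with an amplified
    sample."""
    from nigcmr.simulate import SimulationConfig, simulate_population

    cfg = SimulationConfig(
        seed=21, alpha=1.0, dropout_rate=0.0, false_allele_rate=0.0,
        missing_replicate_rate=0.0, sry_dropout=0.3,
        n_females=20, n_males=30, p_capture=0.5, c_recapture=0.5,
        pattern_class_count=40,
    )
    truth = simulate_population(cfg)
    replicates, samples = corrupt_to_replicates(truth)
    pats = samples[["sample_id"] + cfg.pattern_loci]
    cons = genotyping.consensus_table(replicates, loci=cfg.loci, patterns=pats)
    inds = identity.cluster_individuals(cons, cfg.loci, cfg.pattern_loci)

    # truth-side expectation
    sry = replicates.groupby("sample_id")["sry_amplified"].any()
    src = dict(zip(samples.sample_id, samples.source_individual))
    expected = 0
    by_ind: dict[int, list[str]] = {}
    for s, i in src.items():
        by_ind.setdefault(i, []).append(s)
    for i, ss in by_ind.items():
        if truth.sexes[i] == "M" and any(sry[s] for s in ss):
            expected += sum(not sry[s] for s in ss)
    assert identity.false_female_count(inds) == expected
    assert expected > 0
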