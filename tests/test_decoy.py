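import numpy as np
import pytest

from splicegc import decoy_model as dm
from splicegc.annotation_assembly import ExonInterval, SpliceSiteRecord
from splicegc.folding import make_model
from splicegc.windows_gc import reverse_complement


def site(pos, side="donor", strand="+", chrom="chr1", category="constitutive"):
    exon = ExonInterval(chrom, max(pos - 150, 0), pos + 150, strand)
    return SpliceSiteRecord(chrom, strand, side, pos, category, "g", exon)


def flat_model(side):
    length = dm.window_length(side)
    return dm.SiteScoringModel(side, np.zeros((length, 4)), np.full(4, 0.25))


# --- training and scoring ----------------------------------------------------


def test_train_fixed_position_dominates(rng):
    seqs = []
    for _ in range(80):
        s = list("".join(rng.choice(list("ACGT"), 9)))
        s[3] = "G"  # first intronic position always G
        seqs.append("".join(s))
    model = dm.train_site_model(seqs, "donor")
    assert np.argmax(model.weights[3]) == 2  # G column
    assert model.weights[3, 2] == max(model.weights[3])


def test_train_uniform_gives_near_zero_weights(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(800)]
    model = dm.train_site_model(seqs, "donor")
    assert np.max(np.abs(model.weights)) < 0.5


def test_planted_consensus_beats_mismatches(rng):
    consensus = "CAGGTAAGT"
    seqs = []
    for _ in range(100):
        s = list(consensus)
        if rng.random() < 0.2:  # sprinkle noise at one position
            s[int(rng.integers(9))] = rng.choice(list("ACGT"))
        seqs.append("".join(s))
    model = dm.train_site_model(seqs, "donor")
    best = dm.score_site(model, consensus)
    for i in range(9):
        for c in "ACGT":
            if c != consensus[i]:
                mut = consensus[:i] + c + consensus[i + 1 :]
                assert dm.score_site(model, mut) < best


def test_score_additivity(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(60)]
    model = dm.train_site_model(seqs, "donor")
    s = "CAGGTAAGT"
    manual = sum(model.weights[i, "ACGT".index(c)] for i, c in enumerate(s))
    assert dm.score_site(model, s) == pytest.approx(manual)


def test_training_validation(rng):
    with pytest.raises(ValueError):
        dm.train_site_model(["ACGTACGTA"] * 10, "donor")  # too few
    with pytest.raises(ValueError):
        dm.train_site_model(["ACGT"] * 60, "donor")  # wrong length
    with pytest.raises(ValueError):
        dm.train_site_model(["ACGTACGTA"] * 60, "middle")
    model = dm.train_site_model(["ACGTACGTA"] * 60, "donor")
    with pytest.raises(ValueError):
        dm.score_site(model, "ACGT")


def test_foreground_probabilities_normalized(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 23)) for _ in range(60)]
    model = dm.train_site_model(seqs, "acceptor")
    fg = model.background[None, :] * np.exp2(model.weights)
    assert np.allclose(fg.sum(axis=1), 1.0)


def test_model_serialization_roundtrip(tmp_path, rng):
    seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(60)]
    model = dm.train_site_model(seqs, "donor")
    path = tmp_path / "m.tsv"
    dm.serialize_model(model, path)
    back = dm.load_model(path)
    assert back.side == "donor"
    assert np.allclose(back.weights, model.weights, atol=1e-6)
    assert np.allclose(back.background, model.background, atol=1e-6)


# --- decoy search ------------------------------------------------------------


def make_genome_with_gt(positions, length=3000):
    seq = list("A" * length)
    for p in positions:
        seq[p], seq[p + 1] = "G", "T"
    return {"chr1": "".join(seq)}


def test_find_decoy_nearest_wins():
    p = 1000
    genome = make_genome_with_gt([p, p + 160, p + 290])
    dp = dm.find_decoy(genome, site(p), flat_model("donor"))
    assert dp is not None
    assert dp.distance == 160
    assert dp.decoy.junction_pos == p + 160
    assert dp.decoy.category == "decoy"


def test_find_decoy_zone_bounds():
    p = 1000
    genome = make_genome_with_gt([p, p + 140])  # candidate too close
    assert dm.find_decoy(genome, site(p), flat_model("donor")) is None
    genome = make_genome_with_gt([p, p + 150])
    dp = dm.find_decoy(genome, site(p), flat_model("donor"))
    assert dp is not None and dp.distance == 150
    genome = make_genome_with_gt([p, p + 301])
    assert dm.find_decoy(genome, site(p), flat_model("donor")) is None


def test_find_decoy_no_candidate():
    genome = make_genome_with_gt([1000])
    assert dm.find_decoy(genome, site(1000), flat_model("donor")) is None


def test_find_decoy_threshold_filters():
    p = 1000
    genome = make_genome_with_gt([p, p + 200])
    model = flat_model("donor")
    assert dm.find_decoy(genome, site(p), model, threshold=1.0) is None


def test_find_decoy_acceptor_upstream():
    p = 2000
    seq = list("T" * 3000)
    for q in (p, p - 180):
        seq[q - 1], seq[q] = "A", "G"
    genome = {"chr1": "".join(seq)}
    dp = dm.find_decoy(genome, site(p, side="acceptor"), flat_model("acceptor"))
    assert dp is not None
    assert dp.decoy.junction_pos == p - 180


def test_find_decoy_minus_strand_donor():
    p = 2000
    seq = list("T" * 3000)
    # '-' strand donor: sense GT = genomic AC at (q-1, q); intron runs left
    for q in (p, p - 170):
        seq[q - 1], seq[q] = "A", "C"
    genome = {"chr1": "".join(seq)}
    dp = dm.find_decoy(genome, site(p, strand="-"), flat_model("donor"))
    assert dp is not None
    assert dp.decoy.junction_pos == p - 170
    assert reverse_complement(genome["chr1"][p - 171 : p - 169]) == "GT"


def test_find_decoy_zone_validation():
    genome = make_genome_with_gt([1000])
    with pytest.raises(ValueError):
        dm.find_decoy(genome, site(1000), flat_model("donor"), zone=(300, 150))


# --- recovery and paired comparisons on the planted genome -------------------


@pytest.fixture(scope="module")
def planted(synth, synth_classified):
    cfg, genome, models, truth = synth
    pools = {}
    for side in ("donor", "acceptor"):
        pools[side] = [
            s
            for cat in ("alternative", "constitutive", "skipped")
            for s in synth_classified[cat]
            if s.side == side
        ]
    models_by_side = {
        side: dm.train_site_model(
            [dm.site_scoring_sequence(genome, s) for s in pool], side
        )
        for side, pool in pools.items()
    }
    return cfg, genome, truth, pools, models_by_side


def test_decoy_recovery_on_planted_genome(planted):
    cfg, genome, truth, pools, models_by_side = planted
    planted_decoys = {
        (r.strand, r.side, r.junction_pos): r.decoy_pos for r in truth
    }
    hits = total = 0
    for side, pool in pools.items():
        for s in pool:
            expected = planted_decoys.get((s.strand, s.side, s.junction_pos))
            if expected is None or expected < 0:
                continue
            total += 1
            dp = dm.find_decoy(genome, s, models_by_side[side])
            if dp is not None and dp.decoy.junction_pos == expected:
                hits += 1
    assert total >= 100
    assert hits / total >= 0.95


def test_decoy_constraints_hold(planted):
    cfg, genome, truth, pools, models_by_side = planted
    for side, pool in pools.items():
        for s in pool[:40]:
            dp = dm.find_decoy(genome, s, models_by_side[side])
            if dp is None:
                continue
            assert 150 <= dp.distance <= 300
            assert dp.decoy_score >= 0.0
            assert dm._has_consensus_dinucleotide(genome[s.seq_name], dp.decoy)


def test_decoy_selection_deterministic(planted):
    cfg, genome, truth, pools, models_by_side = planted
    pool = pools["donor"][:20]
    a = [dm.find_decoy(genome, s, models_by_side["donor"]) for s in pool]
    b = [dm.find_decoy(genome, s, models_by_side["donor"]) for s in pool]
    assert a == b


def test_paired_comparison_detects_planted_gc(planted, model37):
    cfg, genome, truth, pools, models_by_side = planted
    pairs = []
    for s in pools["donor"]:
        dp = dm.find_decoy(genome, s, models_by_side["donor"])
        if dp is not None:
            pairs.append(dp)
    res = dm.paired_decoy_comparison(genome, pairs, cfg.flank, model37)
    gc = res["gc"]
    assert gc.paired and gc.mean_a > 0  # real GC exceeds decoy GC
    assert gc.p_value < 0.01
    assert res["mfe"].mean_a < 0  # real windows more stable
    assert res["mfe"].p_value < 0.01


def test_paired_comparison_degenerate_identical():
    # decoy window identical to the real window -> all diffs zero -> p = 1
    block = "ACGTTGCA" * 40
    seq = "A" * 300 + block + block + "A" * 300
    genome = {"chr1": seq}
    real = site(300 + 160)
    pairs = [
        dm.DecoyPair(real, dm._decoy_record(real, 300 + 160 + 320), 320, 0.0, 0.0)
    ] * 10
    res = dm.paired_decoy_comparison(genome, pairs)
    assert res["gc"].p_value == 1.0
    assert res["gc"].mean_a == 0.0


def test_paired_comparison_needs_ten_pairs():
    real = site(1000)
    pair = dm.DecoyPair(real, dm._decoy_record(real, 1200), 200, 0.0, 0.0)
    with pytest.raises(ValueError):
        dm.paired_decoy_comparison({"chr1": "A" * 2000}, [pair])


def test_decoy_tables(tmp_path, planted):
    cfg, genome, truth, pools, models_by_side = planted
    pairs = []
    for s in pools["donor"][:15]:
        dp = dm.find_decoy(genome, s, models_by_side["donor"])
        if dp is not None:
            pairs.append(dp)
    t = tmp_path / "d.tsv"
    dm.write_decoy_table(pairs, t)
    assert len(t.read_text().splitlines()) == len(pairs) + 1
    b = tmp_path / "d.bed"
    dm.write_decoy_bed(pairs, b)
    assert len(b.read_text().splitlines()) == len(pairs)
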