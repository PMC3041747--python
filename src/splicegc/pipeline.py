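"""End-to-end orchestration of the splice-site GC/structure analysis.

``run_full_analysis`` executes the named stages over real inputs
(FASTA + GTF, optional tissue table) or a synthetic genome, writes one TSV
per stage into the output directory, and returns the tables as a bundle.
Every source of randomness is derived from the single configured seed, so a
fixed configuration reproduces byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_assembly as aa
from . import decoy_model as dm
from . import shuffling as sh
from . import stats as st
from . import synthetic_data as syn
from . import windows_gc as wg
from .folding import fold_many, make_model

logger = logging.getLogger(__name__)

SIDES = ("donor", "acceptor")
INTERNAL_CATEGORIES = ("alternative", "constitutive", "skipped")


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for a full run."""

    fasta: Path | None = None
    annotation: Path | None = None
    dialect: str = "gtf"
    tissue_table: Path | None = None
    synthetic: syn.SyntheticConfig | None = None
    flank: int = 70
    temperature_c: float = 37.0
    gc_bins: tuple = st.DEFAULT_GC_BINS
    decoy_zone: tuple[int, int] = (150, 300)
    decoy_threshold: float = 0.0
    pair_max_dist: int = 3000
    n_shuffle: int = 10
    shuffle_subsample: int = 60
    seed: int = 0
    out_dir: Path = Path("splicegc_out")

    def __post_init__(self):
        if self.flank < 1 or self.pair_max_dist < 1 or self.n_shuffle < 1:
            raise ValueError("thresholds must be positive")
        if self.synthetic is None and (self.fasta is None or self.annotation is None):
            raise ValueError("need either a synthetic config or FASTA + annotation")
        for p in (self.fasta, self.annotation, self.tissue_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _site_id(site: aa.SpliceSiteRecord) -> str:
    return f"{site.seq_name}:{site.strand}:{site.side}:{site.junction_pos + 1}"


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns {table name: DataFrame} and writes TSVs."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, st.ComparisonResult] = {}

    # --- stage: inputs ---
    tissue_events = None
    if config.synthetic is not None:
        genome, models, truth = syn.generate_genome_annotation(config.synthetic)
        if config.synthetic.paint_tissue_specific:
            alt = [r for r in truth if r.category == "alternative"]
            ids = [
                f"{r.seq_name}:{r.strand}:{r.side}:{r.junction_pos + 1}" for r in alt
            ]
            tissue_events, _ = syn.generate_tissue_table(
                config.synthetic, ids, [r.tissue_specific for r in alt]
            )
    else:
        genome = wg.read_fasta(config.fasta)
        models = aa.load_annotation(config.annotation, config.dialect)
        if config.tissue_table is not None:
            tissue_events = syn.read_tissue_table(config.tissue_table)
    logger.info("inputs: %d sequences, %d transcripts", len(genome), len(models))

    # --- stage: classification ---
    lists = aa.classify_all(models)
    bundle["site_counts"] = pd.DataFrame(
        [(cat, side, sum(1 for s in recs if s.side == side))
         for cat, recs in lists.items() for side in SIDES],
        columns=["category", "side", "n"],
    )

    # --- stage: windows + folding ---
    model = make_model(config.temperature_c)
    windows: dict[tuple[str, str], list[wg.JunctionWindow]] = {}
    energies: dict[tuple[str, str], np.ndarray] = {}
    for cat, recs in lists.items():
        for side in SIDES:
            sub = [s for s in recs if s.side == side]
            if not sub:
                continue
            ws = wg.extract_windows(genome, sub, config.flank)
            if not ws:
                continue
            windows[(cat, side)] = ws
            energies[(cat, side)] = np.array(
                [r.mfe for r in fold_many([w.sequence for w in ws], model)]
            )
    window_rows = []
    for (cat, side), ws in windows.items():
        for w, e in zip(ws, energies[(cat, side)]):
            window_rows.append(
                dict(site_id=_site_id(w.site), category=cat, side=side,
                     gc_number=w.gc_number, gc_fraction=w.gc_fraction,
                     gc_exonic=w.gc_exonic, gc_intronic=w.gc_intronic,
                     mfe_kcal_mol=e)
            )
    bundle["windows"] = pd.DataFrame(window_rows)

    # --- stage: category comparisons (GC and energy, per side) ---
    for side in SIDES:
        for other in ("constitutive", "skipped"):
            a, b = ("alternative", side), (other, side)
            if a not in windows or b not in windows:
                continue
            gc_a = [w.gc_fraction for w in windows[a]]
            gc_b = [w.gc_fraction for w in windows[b]]
            comparisons[f"gc_alt_vs_{other[:4]}_{side}"] = st.rank_sum_test(
                gc_a, gc_b, label_a="alternative", label_b=other
            )
            comparisons[f"mfe_alt_vs_{other[:4]}_{side}"] = st.rank_sum_test(
                energies[a], energies[b], label_a="alternative", label_b=other
            )

    # --- stage: GC-energy regressions ---
    reg_rows = []
    for (cat, side), ws in windows.items():
        pts = [(w.gc_fraction, e) for w, e in zip(ws, energies[(cat, side)])]
        if len(pts) < 3:
            continue
        try:
            r = st.gc_energy_regression(pts)
        except ValueError:
            continue
        reg_rows.append(
            dict(category=cat, side=side, slope_kcal_mol_per_gc=r.slope,
                 intercept=r.intercept, pearson_r=r.pearson_r,
                 r_squared=r.r_squared, p_value=r.p_value, n=r.n)
        )
    bundle["regressions"] = pd.DataFrame(reg_rows)

    # --- stage: GC-matched bins ---
    matched_rows = []
    for side in SIDES:
        for other in ("constitutive", "skipped"):
            a, b = ("alternative", side), (other, side)
            if a not in windows or b not in windows:
                continue
            groups = {
                "alternative": [
                    (w.gc_number, e) for w, e in zip(windows[a], energies[a])
                ],
                other: [(w.gc_number, e) for w, e in zip(windows[b], energies[b])],
            }
            try:
                per_bin = st.gc_matched_compare(groups, bins=config.gc_bins)
            except ValueError:
                continue
            for (lo, hi), res in per_bin:
                row = dict(side=side, comparison=f"alternative_vs_{other}",
                           gc_bin=f"{lo}-{hi}")
                if res is None:
                    row.update(tested=False, n_a=0, n_b=0, p_value=np.nan)
                else:
                    row.update(tested=True, n_a=res.n_a, n_b=res.n_b,
                               mean_a=res.mean_a, mean_b=res.mean_b,
                               p_value=res.p_value)
                matched_rows.append(row)
    bundle["gc_matched"] = pd.DataFrame(matched_rows)

    # --- stage: distance-controlled pairing ---
    for side in SIDES:
        a, b = ("alternative", side), ("constitutive", side)
        if a not in windows or b not in windows:
            continue
        alt = [(w.site, e) for w, e in zip(windows[a], energies[a])]
        ref = [(w.site, e) for w, e in zip(windows[b], energies[b])]
        try:
            _, res = st.distance_controlled_pairs(alt, ref, config.pair_max_dist)
        except ValueError as exc:
            logger.warning("distance-controlled pairing skipped (%s): %s", side, exc)
            continue
        comparisons[f"paired_mfe_alt_vs_cons_{side}"] = res

    # --- stage: first-exon donors ---
    fa, fc = ("first_alternative", "donor"), ("first_constitutive", "donor")
    if fa in windows and fc in windows:
        comparisons["gc_first_alt_vs_first_cons"] = st.rank_sum_test(
            [w.gc_fraction for w in windows[fa]],
            [w.gc_fraction for w in windows[fc]],
            label_a="first_alternative", label_b="first_constitutive",
        )
        comparisons["mfe_first_alt_vs_first_cons"] = st.rank_sum_test(
            energies[fa], energies[fc],
            label_a="first_alternative", label_b="first_constitutive",
        )
    for first, internal in ((fa, ("alternative", "donor")),
                            (fc, ("constitutive", "donor"))):
        if first in windows and internal in windows:
            comparisons[f"mfe_{first[0]}_vs_internal"] = st.rank_sum_test(
                energies[first], energies[internal],
                label_a=first[0], label_b=f"internal_{internal[0]}",
            )

    # --- stage: long vs short exons ---
    for side in SIDES:
        long_e, short_e, long_gc, short_gc = [], [], [], []
        for cat in INTERNAL_CATEGORIES:
            key = (cat, side)
            if key not in windows:
                continue
            for w, e in zip(windows[key], energies[key]):
                if w.site.exon_length_class == "long":
                    long_e.append(e)
                    long_gc.append(w.gc_fraction)
                else:
                    short_e.append(e)
                    short_gc.append(w.gc_fraction)
        if len(long_e) >= 2 and len(short_e) >= 2:
            comparisons[f"mfe_long_vs_short_{side}"] = st.rank_sum_test(
                long_e, short_e, label_a="long_exon", label_b="short_exon"
            )
            comparisons[f"gc_long_vs_short_{side}"] = st.rank_sum_test(
                long_gc, short_gc, label_a="long_exon", label_b="short_exon"
            )

    # --- stage: tissue specificity ---
    if tissue_events:
        by_id = {}
        for (cat, side), ws in windows.items():
            for w, e in zip(ws, energies[(cat, side)]):
                by_id[_site_id(w.site)] = (w, e)
        ts_gc, ns_gc, ts_e, ns_e = [], [], [], []
        for ev in tissue_events:
            hit = by_id.get(ev.site_id)
            if hit is None:
                continue
            w, e = hit
            call = st.classify_tissue_specific(ev)
            if call == "tissue_specific":
                ts_gc.append(w.gc_fraction)
                ts_e.append(e)
            elif call == "non_tissue_specific":
                ns_gc.append(w.gc_fraction)
                ns_e.append(e)
        if len(ts_gc) >= 2 and len(ns_gc) >= 2:
            comparisons["gc_tissue_specific_vs_non"] = st.rank_sum_test(
                ts_gc, ns_gc, label_a="tissue_specific", label_b="non_specific"
            )
            comparisons["mfe_tissue_specific_vs_non"] = st.rank_sum_test(
                ts_e, ns_e, label_a="tissue_specific", label_b="non_specific"
            )
        else:
            logger.warning("tissue stage skipped: too few classified events")
    else:
        logger.info("no tissue table; tissue stage skipped")

    # --- stage: decoy controls ---
    decoy_rows, profile_rows = [], []
    for side in SIDES:
        pool = [
            s for cat in INTERNAL_CATEGORIES
            for s in lists[cat] if s.side == side
        ]
        if len(pool) < dm.MIN_TRAINING:
            logger.warning("decoy stage skipped (%s): %d sites", side, len(pool))
            continue
        train = []
        for s in pool:
            try:
                train.append(dm.site_scoring_sequence(genome, s))
            except ValueError:
                continue
        site_model = dm.train_site_model(train, side)
        pairs = []
        for s in pool:
            dp = dm.find_decoy(genome, s, site_model, config.decoy_zone,
                               config.decoy_threshold)
            if dp is not None:
                pairs.append(dp)
        if len(pairs) < 10:
            logger.warning("decoy stage skipped (%s): %d pairs", side, len(pairs))
            continue
        for key, res in dm.paired_decoy_comparison(
            genome, pairs, config.flank, model
        ).items():
            comparisons[f"decoy_{key}_{side}"] = res
        decoy_rows += [
            dict(side=side, site_id=_site_id(p.real),
                 decoy_pos_1based=p.decoy.junction_pos + 1, distance_nt=p.distance,
                 real_score_bits=p.real_score, decoy_score_bits=p.decoy_score)
            for p in pairs
        ]
        real_prof = wg.positional_gc_profile(
            [wg.extract_window(genome, p.real, config.flank) for p in pairs]
        )
        decoy_prof = wg.positional_gc_profile(
            [wg.extract_window(genome, p.decoy, config.flank) for p in pairs]
        )
        for which, prof in (("real", real_prof), ("decoy", decoy_prof)):
            profile_rows += [
                dict(side=side, set=which, offset_nt=o, mean_gc_fraction=g, n=prof.n)
                for o, g in zip(prof.offsets, prof.mean_gc)
            ]
    bundle["decoys"] = pd.DataFrame(decoy_rows)
    bundle["positional_gc"] = pd.DataFrame(profile_rows)

    # --- stage: nucleotide-order effect ---
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xD1CE)))
    all_windows = [w for ws in windows.values() for w in ws]
    if all_windows:
        k = min(config.shuffle_subsample, len(all_windows))
        chosen = [all_windows[i] for i in sorted(rng.choice(len(all_windows), k, replace=False))]
        shuffle_results, shuffle_cmps = sh.order_effect_analysis(
            chosen, model, n_reps=config.n_shuffle, seed=config.seed
        )
        comparisons.update(shuffle_cmps)
        bundle["order_effect"] = pd.DataFrame(
            [dict(window_id=r.window_id, native_mfe_kcal_mol=r.native_mfe,
                  mean_mono_mfe=r.mean("mono"), mean_dinuc_mfe=r.mean("dinuc"))
             for r in shuffle_results]
        )

    bundle["comparisons"] = st.comparison_table(comparisons)

    for name, df in bundle.items():
        if df.empty:
            continue
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
    logger.info("run complete in %.1f s; %d tables", time.time() - t0, len(bundle))
    return bundle


EXPECTED_DIRECTIONS = {
    # comparison key prefix -> mean_a should be below (mfe) / above (gc) mean_b
    "mfe_alt_vs": "lower",
    "gc_alt_vs": "higher",
    "decoy_gc": "higher",
    "decoy_mfe": "lower",
    "gc_tissue_specific_vs_non": "higher",
    "mfe_tissue_specific_vs_non": "lower",
    "gc_long_vs_short": "higher",
    "mfe_long_vs_short": "lower",
}


def report_summary(bundle: dict) -> str:
    """One-page textual summary regenerated from the persisted tables only."""
    if not bundle or "comparisons" not in bundle or bundle["comparisons"].empty:
        raise ValueError("empty bundle")
    lines = ["splicegc run summary", "=" * 60]
    counts = bundle.get("site_counts")
    if counts is not None and not counts.empty:
        lines.append("site counts:")
        for _, r in counts.iterrows():
            if r["n"]:
                lines.append(f"  {r['category']:>20s} {r['side']:<8s} n={r['n']}")
    lines.append("comparisons:")
    for _, r in bundle["comparisons"].iterrows():
        direction = ""
        for prefix, want in EXPECTED_DIRECTIONS.items():
            if str(r["comparison"]).startswith(prefix):
                ok = (r["mean_a"] > r["mean_b"]) == (want == "higher")
                direction = " [direction ok]" if ok else " [direction UNEXPECTED]"
                break
        lines.append(
            f"  {r['comparison']:<34s} n=({r['n_a']},{r['n_b']}) "
            f"means=({r['mean_a']:.4g},{r['mean_b']:.4g}) "
            f"p={r['p_value']:.3g}{direction}"
        )
    gm = bundle.get("gc_matched")
    if gm is not None and not gm.empty:
        tested = gm[gm["tested"] == True]  # noqa: E712
        if len(tested):
            frac = (tested["p_value"] > 0.05).mean()
            lines.append(
                f"gc-matched bins: {len(tested)} tested, "
                f"{frac:.0%} non-significant (p > 0.05)"
            )
    return "\n".join(lines) + "\n"
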