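"""End-to-end orchestration: simulate/ingest -> cluster -> subtype ->
screens -> classify, with one JSON run report.

The pipeline is a pure function of (inputs, config, seed).  A single
master seed is fanned out into per-stage child seeds by stable derivation,
so changing one stage's workload (e.g. the number of resampling reps)
never reshuffles another stage's randomness.  Stage outputs are written
before the next stage starts; warnings are collected into the report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .characteristics import characteristics, correlation_screen, membership_indicators
from .classify import stratified_comparison
from .config import PipelineConfig
from .consensus import pac_profile
from .differential import clinical_association, kw_screen, lda_effect_size
from .simulate import CohortDesign, default_trait_table, generate_cohort
from .subtypes import disease_ratio_table, merge_clusters
from .tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonTraitTable,
    join_metadata,
    normalize_tss,
    write_abundance,
)

STAGES = ("simulate", "cluster", "subtype", "differential", "correlate", "classify")


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _digest_frame(frame: pd.DataFrame) -> str:
    payload = frame.to_csv(float_format="%.10g").encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    design: CohortDesign | None = None,
    table: AbundanceTable | None = None,
    meta: list[SampleMetadata] | None = None,
    traits: TaxonTraitTable | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage and return the run report as a plain dict.

    Provide either a synthetic ``design`` or a real ``table`` + ``meta``.
    When ``outdir`` is given, stage tables are written as TSV/CSV as they
    are produced and the report as ``report.json``.
    """
    if (design is None) == (table is None):
        raise ValueError("provide exactly one of design or (table, meta)")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []
    report: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}

    def save(name: str, frame: pd.DataFrame, sep: str = "\t") -> None:
        if out is not None:
            frame.to_csv(out / name, sep=sep, float_format="%.10g")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        truth = None
        if design is not None:
            seed = _stage_seed(config.seed, "simulate")
            table, meta, truth = generate_cohort(design, seed=seed)
            report["stages"]["simulate"] = {
                "seed": seed,
                "n_samples": table.shape[0],
                "n_taxa": table.shape[1],
                "digest": _digest_frame(table.data),
            }
            if out is not None:
                write_abundance(table, out / "abundance.tsv",
                                taxonomy_path=out / "taxonomy.tsv")
                truth.to_frame().to_csv(out / "truth.csv")
        if meta is None:
            raise ValueError("metadata required with a real abundance table")
        meta_frame = join_metadata(table, meta)
        if out is not None:
            meta_frame.to_csv(out / "metadata.csv")
        if traits is None:
            traits = default_trait_table()

        rel = normalize_tss(table)

        # --- consensus clustering + PAC model selection
        seed = _stage_seed(config.seed, "cluster")
        profile, runs = pac_profile(
            rel.values(),
            range(2, config.max_k + 1),
            reps=config.reps,
            p_item=config.p_item,
            p_feature=config.p_feature,
            seed=seed,
            x1=config.pac_x1,
            x2=config.pac_x2,
            n_restarts=config.n_restarts,
        )
        best = runs[profile.best_k]
        pac_frame = pd.DataFrame(
            {"K": list(profile.pac), "PAC": [profile.pac[k] for k in profile.pac]}
        ).set_index("K")
        save("pac_profile.tsv", pac_frame)
        if out is not None:
            np.savetxt(out / "consensus_bestK.tsv", best.consensus,
                       delimiter="\t", fmt="%.6f")
        report["stages"]["cluster"] = {
            "seed": seed,
            "pac": {int(k): float(v) for k, v in profile.pac.items()},
            "best_k": int(profile.best_k),
            "kmeans_retries": int(best.retries),
        }

        # --- disease ratios and subtype merge
        ratio = disease_ratio_table(best.labels, meta_frame)
        save("cluster_ratios.tsv", ratio.frame)
        if config.breakpoints is not None:
            smap = merge_clusters(ratio, breakpoints=config.breakpoints,
                                  band_labels=config.band_labels)
        else:
            smap = merge_clusters(ratio, target_groups=config.target_groups or 4)
        subtype_labels = smap.sample_subtypes(best.labels)
        subtype_ratio = disease_ratio_table(subtype_labels, meta_frame, cluster_prefix="")
        save("subtype_ratios.tsv", subtype_ratio.frame)
        report["stages"]["subtype"] = {
            "assignment": smap.assignment,
            "breakpoints": list(smap.breakpoints),
            "margins": subtype_ratio.margins(),
        }
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            report["stages"]["subtype"]["ari_vs_truth"] = float(
                adjusted_rand_score(truth.loc[table.sample_ids], subtype_labels)
            )

        # --- differential screens
        seed = _stage_seed(config.seed, "differential")
        diff = lda_effect_size(
            rel, subtype_labels, alpha=config.alpha,
            lda_cutoff=config.lda_cutoff, seed=seed,
        )
        save("differential_subtype.tsv", diff.set_index("taxon"))
        screen = kw_screen(rel, subtype_labels, alpha=config.alpha)
        save("kw_screen_subtype.tsv", screen.set_index("taxon"))
        clin = clinical_association(meta_frame, subtype_labels)
        save("clinical_association.tsv", clin.set_index("covariate"))
        report["stages"]["differential"] = {
            "seed": seed,
            "n_significant_kw": int(screen["significant"].sum()),
            "n_lda_hits": int(len(diff)),
        }

        # --- correlations and characteristics
        chars = characteristics(rel, traits)
        save("characteristics.tsv", chars)
        indicators = membership_indicators(subtype_labels)
        indicators.index = chars.index
        corr_taxa = correlation_screen(rel, indicators)
        save("correlations_taxa.tsv", corr_taxa.set_index(["feature", "group"]))
        corr_chars = correlation_screen(chars, indicators)
        save("correlations_characteristics.tsv",
             corr_chars.set_index(["feature", "group"]))
        report["stages"]["correlate"] = {
            "n_taxon_correlations_shown": int(corr_taxa["shown"].sum()),
            "n_characteristic_correlations_shown": int(corr_chars["shown"].sum()),
        }

        # --- stratified classifiers
        seed = _stage_seed(config.seed, "classify")
        clf = stratified_comparison(
            rel,
            meta_frame["disease"],
            subtype_labels,
            train_frac=config.train_frac,
            min_test_total=config.min_test_total,
            alpha=config.alpha,
            seed=seed,
        )
        save("classifier_report.tsv", clf.set_index(["task", "stratum", "split"]))
        report["stages"]["classify"] = {
            "seed": seed,
            "blocks": clf.to_dict(orient="records"),
        }

        collected.extend(str(w.message) for w in caught)

    report["warnings"] = collected
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
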