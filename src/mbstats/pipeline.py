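"""End-to-end analysis pipeline with reproducibility metadata.

``run_pipeline`` wires the stages together: rarefaction, alpha diversity
with covariate-adjusted regression, UniFrac distances, PCoA, kernel
association tests, rank-wise differential abundance, classifier comparison,
and cohort statistics.  Every stage writes a tab-delimited artifact into the
output directory and the manifest records inputs, parameters, and the seeds
actually used, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ValidationError,
    rarefy,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    validate_metadata,
    write_otu_table,
)
from .diversity import alpha_diversity, pcoa, unweighted_unifrac, weighted_unifrac
from .association import alpha_diversity_regression, gower_kernel, kernel_association_test
from .diff_abundance import FilterRule, aggregate_taxa, filter_features, permutation_f_test
from .classification import bootstrap_compare, friedman_compare
from .cohort import cohort_report
from .core import TAXONOMIC_RANKS

logger = logging.getLogger("mbstats")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run.

    Defaults follow common practice for tissue 16S cohorts: rarefaction to
    20,000 reads, 1,000 permutations for permutation tests, 100 bootstrap
    replicates for the classifier comparison, and sequencing batch as the
    adjustment covariate.
    """

    otu_table: str
    tree: str
    taxonomy: str
    metadata: str
    output_dir: str
    rarefaction_depth: int = 20_000
    n_perm: int = 1000
    n_boot: int = 100
    seed: int = 0
    group_col: str = "disease_state"
    label_col: str = "sample_type"
    covariates: tuple[str, ...] = ("batch",)
    da_ranks: tuple[str, ...] = TAXONOMIC_RANKS
    filter_rule: FilterRule = field(default_factory=FilterRule)


def _design_from_metadata(md: pd.DataFrame, columns) -> np.ndarray | None:
    """Dummy-encode metadata columns into a covariate design (no intercept)."""
    if not columns:
        return None
    blocks = []
    for col in columns:
        if col not in md.columns:
            raise ValidationError(f"metadata missing covariate column {col!r}")
        series = md[col]
        if pd.api.types.is_numeric_dtype(series):
            blocks.append(series.to_numpy(dtype=float)[:, None])
        else:
            blocks.append(pd.get_dummies(series, drop_first=True).to_numpy(dtype=float))
    return np.column_stack(blocks)


def _binary_outcome(series: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(series))
    if len(levels) != 2:
        raise ValidationError(
            f"kernel test outcome must be binary, got levels {levels}"
        )
    return (series == levels[1]).to_numpy(dtype=float)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Raises with the failing stage's name on any error; partial outputs are
    flagged in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(4)]
    manifest = {
        "package_version": __version__,
        "inputs": {
            "otu_table": str(config.otu_table),
            "tree": str(config.tree),
            "taxonomy": str(config.taxonomy),
            "metadata": str(config.metadata),
        },
        "parameters": {
            "rarefaction_depth": config.rarefaction_depth,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "stage_seeds": seeds,
            "group_col": config.group_col,
            "covariates": list(config.covariates),
        },
        "stages": {},
        "complete": False,
    }
    stage = "load_inputs"
    try:
        t0 = time.time()
        table = read_otu_table(config.otu_table)
        tree = read_tree(config.tree)
        taxonomy = read_taxonomy(config.taxonomy)
        md = read_metadata(config.metadata)
        validate_metadata(md, table.sample_ids)
        for col in (config.group_col, *config.covariates):
            if col not in md.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        md = md.set_index("sample_id").loc[table.sample_ids].reset_index()
        _log_stage(manifest, stage, t0)

        stage = "rarefy"
        t0 = time.time()
        rtable, dropped = rarefy(table, config.rarefaction_depth, seed=seeds[0])
        rmd = md[md["sample_id"].isin(rtable.sample_ids)].reset_index(drop=True)
        write_otu_table(rtable, out / "rarefied_table.tsv")
        manifest["stages"]["rarefy"] = {"dropped_samples": dropped}
        _log_stage(manifest, stage, t0)

        covs = _design_from_metadata(rmd, config.covariates)
        outcome = _binary_outcome(rmd[config.group_col])

        stage = "alpha_diversity"
        t0 = time.time()
        alpha = pd.DataFrame(
            {
                "observed_otus": alpha_diversity(rtable, "observed_otus"),
                "shannon": alpha_diversity(rtable, "shannon"),
            }
        )
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        reg_rows = []
        for metric in ("observed_otus", "shannon"):
            res = alpha_diversity_regression(alpha[metric], outcome, covariates=covs)
            reg_rows.append(
                {"metric": metric, "group_coefficient": res.statistic,
                 "wald_p": res.p_value}
            )
        pd.DataFrame(reg_rows).to_csv(out / "alpha_regression.tsv", sep="\t", index=False)
        _log_stage(manifest, stage, t0)

        stage = "unifrac"
        t0 = time.time()
        dms = {
            "unweighted": unweighted_unifrac(rtable, tree),
            "weighted": weighted_unifrac(rtable, tree),
        }
        for name, dm in dms.items():
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / f"unifrac_{name}.tsv", sep="\t"
            )
        _log_stage(manifest, stage, t0)

        stage = "pcoa"
        t0 = time.time()
        ord_res = pcoa(dms["unweighted"], k=2)
        coords = ord_res.coordinates.copy()
        coords.to_csv(out / "pcoa_unweighted.tsv", sep="\t", index_label="sample_id")
        pd.DataFrame(
            {
                "eigenvalue": ord_res.eigenvalues[: len(ord_res.proportion_explained)],
                "proportion_explained": ord_res.proportion_explained,
            }
        ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
        _log_stage(manifest, stage, t0)

        stage = "kernel_association"
        t0 = time.time()
        mirkat_rows = []
        for name, dm in dms.items():
            kern = gower_kernel(dm)
            res = kernel_association_test(
                kern, outcome, covariates=covs, n_perm=config.n_perm, seed=seeds[1]
            )
            mirkat_rows.append(
                {"kernel": f"{name}_unifrac", "Q": res.statistic, "p": res.p_value,
                 "n_perm": res.n_permutations, "seed": res.seed}
            )
        pd.DataFrame(mirkat_rows).to_csv(out / "kernel_association.tsv", sep="\t", index=False)
        _log_stage(manifest, stage, t0)

        stage = "differential_abundance"
        t0 = time.time()
        da_frames = []
        group_labels = rmd[config.group_col]
        for rank in config.da_ranks:
            agg = aggregate_taxa(rtable, taxonomy, rank)
            try:
                filtered, _removed = filter_features(agg, config.filter_rule)
            except ValidationError:
                continue
            res = permutation_f_test(
                filtered, group_labels, covariates=covs,
                n_perm=config.n_perm, seed=seeds[2],
            )
            res.insert(0, "rank", rank)
            da_frames.append(res)
        pd.concat(da_frames, ignore_index=True).to_csv(
            out / "differential_abundance.tsv", sep="\t", index=False
        )
        _log_stage(manifest, stage, t0)

        stage = "classification"
        t0 = time.time()
        labels = rmd[config.label_col]
        if labels.nunique() < 2:
            labels = group_labels
        genus = aggregate_taxa(rtable, taxonomy, "genus")
        errors = bootstrap_compare(
            genus.proportions(), labels.to_numpy(),
            n_boot=config.n_boot, seed=seeds[3],
        )
        pd.DataFrame(
            errors.errors, columns=["random_forest_error", "majority_class_error"]
        ).to_csv(out / "classification_errors.tsv", sep="\t", index_label="replicate")
        fr = friedman_compare(errors)
        (out / "classification_friedman.json").write_text(
            json.dumps({"statistic": fr.statistic, "p_value": fr.p_value,
                        "n_boot": errors.n_boot, "seed": errors.seed}, indent=2)
        )
        _log_stage(manifest, stage, t0)

        stage = "cohort_stats"
        t0 = time.time()
        subj = rmd.drop_duplicates("subject_id")
        report = cohort_report(
            subj, [("batch", "nominal")], group_col=config.group_col
        )
        report.to_csv(out / "cohort_stats.tsv", sep="\t", index=False)
        _log_stage(manifest, stage, t0)

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _log_stage(manifest: dict, stage: str, t0: float) -> None:
    elapsed = time.time() - t0
    manifest["stages"].setdefault(stage, {})["seconds"] = round(elapsed, 3)
    logger.info("stage=%s elapsed=%.2fs", stage, elapsed)
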