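"""End-to-end pipeline: decompose -> fit -> predict/impute -> network -> coevolve.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs and
stage settings; :func:`run_pipeline` executes the stages in order, writes
each stage's artifacts to the output directory, and stamps the run with the
resolved configuration, package version, seeds and output hashes so a rerun
with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coevolution import likelihood_ratio_test, run_mcmc, transition_rate_report
from .decomposition import decompose, interaction_features
from .io import (
    read_gene_trees,
    read_matrix,
    read_species_tree,
    read_trait_table,
    write_trait_table,
)
from .network import min_bic_forest, partial_correlations
from .traitmodel import (
    CVConfig,
    fit_continuous_trait,
    fit_discrete_trait,
    impute_missing_terminals,
    predict_branches,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    species_tree: str
    trait_table: str
    trait_schema: dict[str, str]
    gene_trees: str | None = None
    gene_matrix: str | None = None
    time_calibrated: bool = True
    pseudocount: float = 1e-9
    fill_policy: str = "zero-log"
    min_coverage: float = 0.8
    folds: int = 10
    seed: int = 0
    one_se: bool = True
    traits_to_fit: list[str] | None = None
    network_traits: list[str] | None = None
    coevolution_pair: list[str] | None = None
    mcmc_iterations: int = 0
    out_dir: str = "ratetrait_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


@dataclass
class _Stage:
    """Run a named stage, halting the pipeline with a stage-named error."""

    name: str
    outputs: list[Path] = field(default_factory=list)

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        for p in self.outputs:
            logger.info("stage %s: wrote %s (sha1 %s)", self.name, p, _sha1(p))
        return False


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cv = CVConfig(folds=config.folds, seed=config.seed, one_se=config.one_se)

    with _Stage("io") as st:
        tree = read_species_tree(config.species_tree, config.time_calibrated)
        if config.gene_matrix:
            M = read_matrix(config.gene_matrix, species=tree)
        elif config.gene_trees:
            M = read_gene_trees(config.gene_trees, tree, config.min_coverage)
        else:
            raise ValueError("config needs gene_trees or gene_matrix")
        traits = read_trait_table(config.trait_table, config.trait_schema)

    with _Stage("decompose") as st:
        D = decompose(M, pseudocount=config.pseudocount)
        reff = out / "branch_effects.tsv"
        D.branch_effects.to_csv(reff, sep="\t", header=["R"], index_label="branch")
        geff = out / "gene_effects.tsv"
        D.gene_effects.to_csv(geff, sep="\t", header=["r"], index_label="gene")
        inter = out / "log_interactions.tsv"
        D.log_interactions.to_csv(inter, sep="\t", na_rep="NA", index_label="gene")
        st.outputs += [reff, geff, inter]
        X = interaction_features(
            D, fit_branches=tree.terminal_branches, fill=config.fill_policy
        )

    fit_traits = config.traits_to_fit or [
        t for t in config.trait_schema if t in traits.values.columns
    ]
    models = {}
    with _Stage("fit") as st:
        for trait in fit_traits:
            fam = config.trait_schema[trait]
            fit = fit_continuous_trait if fam == "continuous" else fit_discrete_trait
            model = fit(X, traits, trait, cv=cv)
            models[trait] = model
            mp = out / f"model_{trait}.json"
            model.to_json(mp)
            st.outputs.append(mp)

    combined = traits.copy()
    internal = [b for b in tree.internal_branches if b in X.X.index]
    anc_rows = pd.DataFrame(
        np.nan, index=internal, columns=combined.values.columns
    )
    combined.values = pd.concat([combined.values, anc_rows])
    combined.provenance = pd.concat(
        [combined.provenance, anc_rows.astype(object).where(anc_rows.notna())]
    )

    with _Stage("predict") as st:
        pred_rows = []
        for trait, model in models.items():
            pred = predict_branches(model, X, internal)
            vals = (
                pred.values
                if model.family == "linear-on-log"
                else pred.hard_calls.astype(float)
            )
            combined.values.loc[internal, trait] = vals
            combined.provenance.loc[internal, trait] = "predicted-ancestral"
            for b in internal:
                row = {"branch": b, "trait": trait, "predicted": vals[b]}
                if model.family == "logistic":
                    row["probability"] = pred.values[b]
                pred_rows.append(row)
        pp = out / "ancestral_predictions.tsv"
        pd.DataFrame(pred_rows).to_csv(pp, sep="\t", index=False)
        st.outputs.append(pp)

    with _Stage("impute") as st:
        for trait, model in models.items():
            combined = impute_missing_terminals(model, X, combined)
        tp = out / "trait_table_full.tsv"
        combined.validate()
        write_trait_table(combined, tp)
        st.outputs.append(tp)

    with _Stage("network") as st:
        net_traits = config.network_traits or fit_traits
        if len(net_traits) >= 2:
            res = partial_correlations(combined, net_traits)
            pcp = out / "partial_correlations.tsv"
            res.partial.to_csv(pcp, sep="\t", index_label="trait")
            graph = min_bic_forest(combined, net_traits)
            ep = out / "network_edges.tsv"
            graph.write_edge_tsv(ep)
            st.outputs += [pcp, ep]

    if config.coevolution_pair:
        with _Stage("coevolve") as st:
            a, b = config.coevolution_pair
            tt = combined.values.loc[tree.terminal_branches, [a, b]]
            tips = {
                taxon: (row[a], row[b])
                for taxon, row in tt.iterrows()
                if not row.isna().any()
            }
            lrt = likelihood_ratio_test(tree, tips, seed=config.seed)
            report = transition_rate_report(lrt["dependent"])
            if config.mcmc_iterations > 0:
                trace = run_mcmc(
                    tree, tips, "dependent",
                    iterations=config.mcmc_iterations, seed=config.seed,
                )
                report = transition_rate_report(lrt["dependent"], trace)
                trp = out / "mcmc_trace.tsv"
                trace.rates.assign(loglik=trace.loglik).to_csv(trp, sep="\t", index=False)
                st.outputs.append(trp)
            rp = out / "coevolution_rates.tsv"
            report.to_csv(rp, sep="\t", index=False)
            sp = out / "coevolution_test.tsv"
            pd.DataFrame(
                [
                    {
                        "loglik_independent": lrt["independent"].loglik,
                        "loglik_dependent": lrt["dependent"].loglik,
                        "statistic": lrt["statistic"],
                        "df": lrt["df"],
                        "pvalue": lrt["pvalue"],
                    }
                ]
            ).to_csv(sp, sep="\t", index=False)
            st.outputs += [rp, sp]

    stamp = {
        "package": "ratetrait",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(stamp, fh, sort_keys=True)
    return out
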