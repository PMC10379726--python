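"""End-to-end orchestration: simulate/load -> diversity -> community typing
-> trajectory & survival -> differential abundance -> metabolome -> omics
integration, from a single config, with a machine-readable results bundle.

Every stage writes its tables under the bundle directory; a run manifest
records versions, seeds, parameters and per-file checksums so a re-run with
the same config is verifiably identical (timestamps excluded).  All
randomness flows from one master seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import faith_pd_samples
from .dmm import order_fcts, select_dmm
from .integration import (cluster_heatmap_order, fct_association_table,
                          interdomain_matrix, treatment_association)
from .metabolome import (baseline_shift_tests, bile_acid_ratios, fit_pls,
                         p_corr, select_discriminant, validate_pls, vip)
from .stats import compare_features, wmw_test
from .synthetic import (CohortConfig, default_genus_tree_newick,
                        generate_cohort)
from .tables import (KOAbundanceMatrix, MetaboliteMatrix, SampleTable,
                     TaxaCountMatrix, read_count_table, read_newick,
                     rarefy_matrix)
from .trajectory import build_transition_graph, cox_binary, fct_event_table, km_curve

log = logging.getLogger("fctpath.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Either ``input_dir`` (TSV tables named as written by
    ``SyntheticCohort.write_tables`` plus ``tree.nwk``) or a synthetic block
    must be present — not neither.  ``stratum`` filters the arm-contrast
    stages (EE, LE or all); community typing always uses all samples.
    """

    outdir: str = "results/bundle"
    synthetic: bool = True
    cohort_overrides: dict = field(default_factory=dict)
    input_dir: str | None = None
    stratum: str = "EE"
    visits: tuple[str, ...] = ("V1", "V3", "V6")
    target_fct: int = 3
    k_min: int = 2
    k_max: int = 10
    dmm_repeats: int = 10
    rarefy_depth: int | None = None
    pls_components: int = 2
    pls_visits: tuple[str, ...] = ("V3", "V6")
    n_permutations: int = 50
    cv_folds: int = 7
    min_detect: int = 3
    fdr: float = 0.10
    display_threshold: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic and self.input_dir is None:
            raise PipelineError("config error: need input_dir or a synthetic block")
        if self.stratum not in ("EE", "LE", "all"):
            raise PipelineError(f"config error: unknown stratum {self.stratum!r}")
        if self.k_min > self.k_max or self.k_min < 1:
            raise PipelineError("config error: bad K range")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config error: unknown keys {sorted(unknown)}")
        for key in ("visits", "pls_visits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False,
           index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage=%s event=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s event=done", name)
            return out
        return wrapped
    return deco


@_stage("load")
def _load_inputs(cfg: PipelineConfig, rng_seed: int):
    if cfg.synthetic:
        cohort_cfg = CohortConfig(**cfg.cohort_overrides)
        cohort = generate_cohort(cohort_cfg, seed=rng_seed)
        tree = read_newick(default_genus_tree_newick())
        return (cohort.metadata, cohort.counts, cohort.metabolites, cohort.ko,
                tree, cohort.truth_fct)
    d = Path(cfg.input_dir)
    metadata = SampleTable.from_tsv(d / "metadata.tsv")
    counts = read_count_table(d / "genus_counts.tsv")
    metabolites = MetaboliteMatrix.from_tsv(d / "metabolites.tsv")
    ko = KOAbundanceMatrix.from_tsv(d / "ko_abundance.tsv")
    tree = read_newick(d / "tree.nwk")
    return metadata, counts, metabolites, ko, tree, None


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run every stage and write the results bundle; returns the results.

    Deterministic for fixed seeds: the master seed spawns one substream per
    stage, so changing one stage's parameters does not perturb another's
    draws.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    ss = np.random.SeedSequence(cfg.seed)
    sub = {name: int(child.generate_state(1)[0] % (2**31 - 1))
           for name, child in zip(
               ("simulate", "rarefy", "dmm", "pls"), ss.spawn(4))}

    results: dict = {}
    try:
        metadata, counts, metabolites, ko, tree, truth = _load_inputs(
            cfg, sub["simulate"])
        meta = metadata.frame.set_index("sample_id")
        if cfg.synthetic:
            cohort_dir = out / "inputs"
            cohort_dir.mkdir(exist_ok=True)
            metadata.to_tsv(cohort_dir / "metadata.tsv")
            counts.to_tsv(cohort_dir / "genus_counts.tsv")
            metabolites.to_tsv(cohort_dir / "metabolites.tsv")
            ko.to_tsv(cohort_dir / "ko_abundance.tsv")
            (cohort_dir / "tree.nwk").write_text(default_genus_tree_newick())

        strat_ids = (meta.index if cfg.stratum == "all"
                     else meta.index[meta["stratum"] == cfg.stratum])

        # -- diversity (rarefied) --------------------------------------------
        rarefied = rarefy_matrix(counts, depth=cfg.rarefy_depth, seed=sub["rarefy"])
        pd_series = faith_pd_samples(rarefied, tree)
        div = pd_series.rename_axis("sample_id").reset_index()
        div = div.merge(metadata.frame, on="sample_id")
        _write(div, out / "diversity.tsv")
        div_tests = []
        for visit in ("V0", *cfg.visits):
            at = div[(div["visit"] == visit) & div["sample_id"].isin(strat_ids)]
            if at["arm"].nunique() == 2:
                x = at.loc[at["arm"] == "control", "faith_pd"]
                y = at.loc[at["arm"] == "test", "faith_pd"]
                div_tests.append({"visit": visit, "p_value": wmw_test(x, y)})
        results["diversity_tests"] = pd.DataFrame(div_tests)
        _write(results["diversity_tests"], out / "diversity_arm_tests.tsv")
        log.info("stage=diversity event=done n=%d", len(div))

        # -- community typing (all samples, non-rarefied) --------------------
        model = select_dmm(counts, k_range=range(cfg.k_min, cfg.k_max + 1),
                           repeats=cfg.dmm_repeats, seed=sub["dmm"])
        assignment = order_fcts(model, metadata)
        results["dmm_model"] = model
        results["assignment"] = assignment
        _write(model.selection_table, out / "dmm_evidence_by_k.tsv")
        _write(assignment.to_frame(), out / "fct_assignment.tsv")
        log.info("stage=typecluster event=done K=%d", model.K)

        # -- trajectory network & survival -----------------------------------
        graph = build_transition_graph(assignment, metadata,
                                       display_threshold=cfg.display_threshold)
        _write(graph.nodes, out / "transition_nodes.tsv")
        _write(graph.edges, out / "transition_edges.tsv")
        (out / "transition_graph.dot").write_text(graph.to_dot())
        strat_meta = SampleTable(metadata.frame[
            metadata.frame["sample_id"].isin(strat_ids)])
        records = fct_event_table(assignment, strat_meta, cfg.target_fct)
        _write(records, out / "survival_records.tsv")
        for arm in ("control", "test"):
            _write(km_curve(records[records["arm"] == arm]),
                   out / f"km_{arm}.tsv")
        cox = cox_binary(records)
        results["cox"] = cox
        (out / "cox_result.json").write_text(json.dumps({
            "hazard_ratio": cox.hazard_ratio, "ci_low": cox.ci_low,
            "ci_high": cox.ci_high, "score_chi2": cox.score_chi2,
            "score_p": cox.score_p, "n": cox.n, "n_events": cox.n_events,
        }, indent=2))
        log.info("stage=trajectory event=done hr=%.3f p=%.4f",
                 cox.hazard_ratio, cox.score_p)

        # -- differential abundance (relative genus abundance per visit) -----
        rel = counts.counts.div(counts.counts.sum(axis=1), axis=0)
        arms = meta["arm"]
        visits_col = meta["visit"]
        da_frames = []
        for visit in cfg.visits:
            at = visits_col[visits_col == visit].index.intersection(strat_ids)
            sub_rel = rel.loc[rel.index.intersection(at)]
            if sub_rel.empty or arms.loc[sub_rel.index].nunique() != 2:
                continue
            res = compare_features(sub_rel, arms, adjust=True)
            res["visit"] = visit
            da_frames.append(res)
        results["diff_abundance"] = pd.concat(da_frames, ignore_index=True)
        _write(results["diff_abundance"], out / "diff_abundance.tsv")

        # -- metabolome: PLS on age + treatment at the selected visits --------
        mtb = metabolites.concentrations
        pls_ids = meta.index[meta["visit"].isin(cfg.pls_visits)]
        pls_ids = pls_ids.intersection(strat_ids).intersection(mtb.index)
        X = mtb.loc[pls_ids]
        Y = np.column_stack([
            meta.loc[pls_ids, "age"].to_numpy(dtype=float),
            (meta.loc[pls_ids, "arm"] == "test").to_numpy(dtype=float),
        ])
        pls = fit_pls(X.to_numpy(), Y, n_components=cfg.pls_components,
                      feature_ids=list(X.columns))
        vips = vip(pls)
        pcorr = p_corr(pls, X.to_numpy(), component=min(2, pls.n_components))
        q2, perm_p = validate_pls(X.to_numpy(), Y, cfg.pls_components,
                                  folds=cfg.cv_folds,
                                  n_permutations=cfg.n_permutations,
                                  seed=sub["pls"])
        wmw_ps = pd.Series({
            met: wmw_test(
                X.loc[arms.loc[pls_ids] == "control", met].dropna(),
                X.loc[arms.loc[pls_ids] == "test", met].dropna())
            for met in X.columns
        })
        decisions = select_discriminant(vips, pcorr, wmw_ps)
        results["pls"] = pls
        results["pls_q2"] = q2
        results["pls_perm_p"] = perm_p
        results["decisions"] = decisions
        _write(decisions.reset_index(), out / "metabolite_decisions.tsv")
        (out / "pls_validation.json").write_text(json.dumps(
            {"q2y": q2, "permutation_p": perm_p, "r2y": pls.r2y,
             "n_components": pls.n_components}, indent=2))
        log.info("stage=metabolome event=done q2=%.3f selected=%d",
                 q2, int(decisions["selected"].sum()))

        # -- bile-acid conjugation ratios and baseline shifts -----------------
        ratios = bile_acid_ratios(mtb)
        _write(ratios, out / "bile_acid_ratios.tsv", index=True,
               index_label="sample_id")
        shift_rows = []
        for ratio_name in ratios.columns:
            for arm in ("control", "test"):
                ps = baseline_shift_tests(
                    ratios[ratio_name].loc[ratios.index.intersection(strat_ids)],
                    metadata, arm)
                for visit, pval in ps.items():
                    shift_rows.append({"ratio": ratio_name, "arm": arm,
                                       "visit": visit, "p_value": pval})
        results["baseline_shifts"] = pd.DataFrame(shift_rows)
        _write(results["baseline_shifts"], out / "bile_acid_baseline_shifts.tsv")

        # -- omics integration -------------------------------------------------
        int_ids = meta.index[meta["visit"].isin(cfg.pls_visits)]
        int_ids = int_ids.intersection(strat_ids)
        selected_mets = decisions.index[decisions["selected"]].tolist()
        int_mtb = mtb[selected_mets] if selected_mets else mtb
        int_mtb = int_mtb.join(ratios[["ba_cba", "ca_cca"]])
        corr = interdomain_matrix(ko.abundances.loc[ko.abundances.index.intersection(int_ids)],
                                  int_mtb.loc[int_mtb.index.intersection(int_ids)],
                                  min_detect=cfg.min_detect,
                                  fdr_threshold=cfg.fdr)
        results["correlation"] = corr
        _write(corr.tau, out / "integration_tau.tsv", index=True, index_label="ko")
        _write(corr.p, out / "integration_p.tsv", index=True, index_label="ko")
        _write(corr.q, out / "integration_q.tsv", index=True, index_label="ko")
        _write(corr.significant, out / "integration_significant.tsv",
               index=True, index_label="ko")
        row_order, col_order = cluster_heatmap_order(corr)
        (out / "integration_leaf_order.json").write_text(json.dumps(
            {"rows": list(map(str, row_order)),
             "columns": list(map(str, col_order))}, indent=2))
        sidebars = []
        fct_series = assignment.labels
        for visit in cfg.pls_visits:
            for label, frame in (("ko", ko.abundances), ("metabolite", int_mtb)):
                ids = frame.index.intersection(strat_ids)
                tr = treatment_association(frame.loc[ids], arms, visits_col,
                                           visit, fdr_threshold=cfg.fdr)
                tr["domain"] = label
                tr["kind"] = "treatment"
                sidebars.append(tr)
                fa = fct_association_table(frame.loc[ids], fct_series,
                                           visits_col, visit,
                                           fdr_threshold=cfg.fdr)
                fa["domain"] = label
                fa["kind"] = "fct"
                sidebars.append(fa)
        results["sidebars"] = pd.concat(sidebars, ignore_index=True)
        _write(results["sidebars"], out / "integration_sidebars.tsv")
        log.info("stage=integrate event=done cells=%d", corr.tau.size)

        # -- manifest ----------------------------------------------------------
        files = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name not in ("manifest.json", "run.log"))
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "substream_seeds": sub,
            "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(cfg).items()},
            "selected_K": results["dmm_model"].K,
            "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def main(argv: list[str] | None = None) -> int:
    """``python -m fctpath.pipeline --config c.toml`` entry point."""
    import argparse

    ap = argparse.ArgumentParser(description="Run the full analysis pipeline")
    ap.add_argument("--config", required=False, help="TOML config file")
    ap.add_argument("--outdir", default=None)
    ap.add_argument("--seed", type=int, default=None)
    args = ap.parse_args(argv)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")
    try:
        cfg = PipelineConfig.from_toml(args.config) if args.config else PipelineConfig()
        if args.outdir:
            cfg.outdir = args.outdir
        if args.seed is not None:
            cfg.seed = args.seed
    except PipelineError as exc:
        print(exc, file=sys.stderr)
        return 2
    try:
        run_full_analysis(cfg)
    except PipelineError as exc:
        print(exc, file=sys.stderr)
        return 3
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
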