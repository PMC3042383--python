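"""Config-driven orchestration: simulate -> predict -> combine -> evaluate.

A pipeline run is fully described by a YAML config with blocks
``genomes`` (synthetic genome generation), ``benchmark`` (read lengths,
reads per stratum), ``predictors`` (built-in baseline, seeded mocks, or
ingested prediction files), ``combinations`` (Boolean/consensus rules)
and ``report``.  Replicates draw independent benchmark samples from
seeds derived deterministically from the master seed, and the report
aggregates the replicate tables with mean and standard deviation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from fragbench.combine import (
    CombinationRule,
    combine_predictions,
    upper_bound_error,
)
from fragbench.errors import ConfigurationError, FormatError
from fragbench.fragsim import BenchmarkSet, build_benchmark
from fragbench.metrics import metric_table, roc_auc
from fragbench.predict import (
    PredictionSet,
    baseline_orf_predictor,
    mock_predictor,
    parse_predictions,
    train_codon_model,
)
from fragbench.syngen import GenomeSimConfig, generate_genomes

log = logging.getLogger("fragbench")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see from_yaml for the file layout)."""

    genomes: GenomeSimConfig
    read_lengths: tuple[int, ...]
    n_per_type: int
    predictors: tuple[dict, ...]
    combinations: tuple[CombinationRule, ...]
    seed: int = 0
    replicates: int = 1
    allow_replacement: bool = False
    outdir: Path = Path("fragbench_out")
    per_type: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "PipelineConfig":
        try:
            gb = dict(cfg.get("genomes", {}))
            for key in ("gene_length", "intergenic_length"):
                if key in gb:
                    gb[key] = tuple(gb[key])
            seed = int(cfg.get("seed", 0))
            gb.setdefault("seed", seed)
            genomes = GenomeSimConfig(**gb)
            bench = cfg.get("benchmark", {})
            read_lengths = tuple(int(x) for x in bench.get("read_lengths", range(100, 701, 100)))
            n_per_type = int(bench.get("n_per_type", 1000))
            predictors = tuple(dict(p) for p in cfg.get("predictors", []))
            combos = []
            for c in cfg.get("combinations", []):
                combos.append(CombinationRule(op=c["op"], members=tuple(c["members"])))
            report = cfg.get("report", {})
            config = cls(
                genomes=genomes,
                read_lengths=read_lengths,
                n_per_type=n_per_type,
                predictors=predictors,
                combinations=tuple(combos),
                seed=seed,
                replicates=int(cfg.get("replicates", 1)),
                allow_replacement=bool(bench.get("allow_replacement", False)),
                outdir=Path(cfg.get("outdir", "fragbench_out")),
                per_type=bool(report.get("per_type", True)),
                raw=dict(cfg),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid pipeline config: {exc}") from exc
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        return cls.from_mapping(cfg)

    def validate(self) -> None:
        self.genomes.validate()
        names = []
        for p in self.predictors:
            if "name" not in p or p.get("kind") not in ("mock", "baseline", "file"):
                raise ConfigurationError(
                    f"predictor entries need a name and kind in mock|baseline|file: {p}"
                )
            names.append(p["name"])
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate predictor names in {names}")
        known = set(names)
        for rule in self.combinations:
            unresolved = [m for m in rule.members if m not in known]
            if unresolved:
                raise ConfigurationError(
                    f"combination {rule.name} references unknown members {unresolved} "
                    "(members must be predictors or previously defined combinations)"
                )
            known.add(rule.name)

    def manifest(self) -> dict:
        digest = hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()
        from fragbench import __version__  # deferred: avoids import cycle

        return {
            "fragbench_version": __version__,
            "config_sha256": digest,
            "seed": self.seed,
            "replicates": self.replicates,
            "read_lengths": list(self.read_lengths),
            "n_per_type": self.n_per_type,
        }


def _build_predictors(
    config: PipelineConfig, bench: BenchmarkSet, genomes, rep_seed: np.random.SeedSequence
) -> list[PredictionSet]:
    psets = []
    children = rep_seed.spawn(len(config.predictors))
    for p, child in zip(config.predictors, children):
        kind = p["kind"]
        if kind == "mock":
            pset = mock_predictor(
                bench,
                sens=float(p.get("sens", 0.8)),
                spec=float(p.get("spec", 0.8)),
                coord_noise_sd=float(p.get("coord_noise_sd", 0.0)),
                seed=child,
                name=p["name"],
            )
        elif kind == "baseline":
            model = train_codon_model(
                genomes,
                pseudocount=float(p.get("pseudocount", 1.0)),
                min_orf_len=int(p.get("min_orf_len", 60)),
                score_threshold=float(p.get("score_threshold", 0.1)),
            )
            pset = baseline_orf_predictor(bench.fragments, model, name=p["name"])
        else:  # file
            pset = parse_predictions(
                p["path"], format=p.get("format", "tsv"), predictor_name=p["name"]
            )
            pset.validate_against(bench)
        psets.append(pset)
    return psets


def _suggested_methods(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per read length, the method maximizing accuracy, annotation error as tie-break."""
    rows = []
    pooled = metrics[metrics["stratum"] == "ALL"]
    for L, group in pooled.groupby("read_length"):
        g = group.sort_values(
            by=["accuracy", "mean_annotation_error", "method"],
            ascending=[False, True, True],
            na_position="last",
        )
        best = g.iloc[0]
        rows.append(
            {
                "read_length": L,
                "method": best["method"],
                "accuracy": best["accuracy"],
                "mean_annotation_error": best["mean_annotation_error"],
            }
        )
    return pd.DataFrame(rows)


def _upper_bound_table(
    bench: BenchmarkSet, singles: Sequence[PredictionSet]
) -> pd.DataFrame:
    rows = []
    for L in bench.read_lengths:
        frags = bench.stratum(read_length=L)
        truth = {f.read_id: f.is_coding for f in frags}
        calls = {
            p.predictor_name: {f.read_id: p.is_coding(f.read_id) for f in frags}
            for p in singles
        }
        errors = {
            name: np.mean([c[rid] != truth[rid] for rid in truth])
            for name, c in calls.items()
        }
        rows.append(
            {
                "read_length": L,
                "upper_bound_error": upper_bound_error(calls, truth),
                "min_single_error": min(errors.values()),
                **{f"error_{k}": v for k, v in errors.items()},
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run the full benchmark pipeline; returns the report bundle.

    The bundle maps replicate index -> {"metrics", "auc", "roc",
    "upper_bound", "per_type_accuracy", "suggested"} DataFrames, plus
    "summary" (mean/sd of the pooled rates across replicates) and
    "manifest".  With write=True every table lands under config.outdir
    as TSV, the manifest as JSON.
    """
    log.info("generating %d synthetic genomes", config.genomes.n_genomes)
    genomes = generate_genomes(config.genomes)
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replicates)
    bundle: dict = {"replicates": {}}
    summary_frames = []
    for rep, rep_seed in enumerate(rep_seeds):
        log.info("replicate %d: building benchmark", rep)
        bench_seed, pred_seed = rep_seed.spawn(2)
        bench = build_benchmark(
            genomes,
            config.read_lengths,
            config.n_per_type,
            seed=int(bench_seed.generate_state(1)[0] % (2**31)),
            allow_replacement=config.allow_replacement,
        )
        log.info("replicate %d: running %d predictors", rep, len(config.predictors))
        psets = _build_predictors(config, bench, genomes, pred_seed)
        singles = list(psets)
        disjoint: dict[str, int] = {}
        for rule in config.combinations:
            log.info("replicate %d: combining %s", rep, rule.name)
            combined, n_disjoint = combine_predictions(psets, rule, bench=bench)
            disjoint[rule.name] = n_disjoint
            psets.append(combined)
        log.info("replicate %d: evaluating", rep)
        metrics = metric_table(
            bench, psets, per_type=config.per_type, disjoint_counts=disjoint
        )
        auc_rows, roc_rows = [], []
        for pset in psets:
            pts = []
            for L in bench.read_lengths:
                r = metrics[
                    (metrics["method"] == pset.predictor_name)
                    & (metrics["read_length"] == L)
                    & (metrics["stratum"] == "ALL")
                ].iloc[0]
                if np.isnan(r["sensitivity"]) or np.isnan(r["specificity"]):
                    continue
                f, t = 1.0 - r["specificity"], r["sensitivity"]
                pts.append((f, t))
                roc_rows.append(
                    {"method": pset.predictor_name, "read_length": L, "fpr": f, "tpr": t}
                )
            auc_rows.append(
                {"method": pset.predictor_name, "auc": roc_auc(pts) if pts else np.nan}
            )
        per_type_acc = (
            metrics[metrics["stratum"].isin(list("ABCD"))]
            .groupby(["method", "stratum"], as_index=False)["accuracy"]
            .mean()
        )
        rep_tables = {
            "metrics": metrics,
            "roc": pd.DataFrame(roc_rows),
            "auc": pd.DataFrame(auc_rows),
            "upper_bound": _upper_bound_table(bench, singles),
            "per_type_accuracy": per_type_acc,
            "suggested": _suggested_methods(metrics),
        }
        bundle["replicates"][rep] = rep_tables
        pooled = metrics[metrics["stratum"] == "ALL"].copy()
        pooled["replicate"] = rep
        summary_frames.append(pooled)
    all_reps = pd.concat(summary_frames, ignore_index=True)
    summary = (
        all_reps.groupby(["method", "read_length"], as_index=False)
        .agg(
            sensitivity_mean=("sensitivity", "mean"),
            sensitivity_sd=("sensitivity", "std"),
            specificity_mean=("specificity", "mean"),
            specificity_sd=("specificity", "std"),
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            annotation_error_mean=("mean_annotation_error", "mean"),
            annotation_error_sd=("mean_annotation_error", "std"),
        )
    )
    bundle["summary"] = summary
    bundle["manifest"] = config.manifest()
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rep, tables in bundle["replicates"].items():
            rep_dir = outdir / f"rep{rep}"
            rep_dir.mkdir(exist_ok=True)
            for name, df in tables.items():
                df.to_csv(rep_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.6g")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
        log.info("report written to %s", outdir)
    return bundle


def ingest_real_reads(fasta_path, preds: PredictionSet) -> pd.DataFrame:
    """Classify truth-free reads by the shape of their predicted interval.

    Without annotation the fragment type is inferred from how the
    predicted coding interval touches the read edges: right edge only
    means the gene continues past the read (A-like, gene start present);
    left edge only means the gene ends inside the read (C-like); both
    edges, or an internal complete gene, is B-like; no prediction is D.
    Returns one row per class with count and percentage, plus the
    coding/non-coding ratio in the attrs.
    """
    lengths = {r.id: len(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    unknown = set(preds.predictions) - set(lengths)
    if unknown:
        raise FormatError(
            f"predictions reference reads absent from {fasta_path}: "
            f"{sorted(unknown)[:10]}"
        )
    tally = {"A-like": 0, "B-like": 0, "C-like": 0, "D": 0}
    for rid, L in lengths.items():
        pred = preds.get(rid)
        if not pred.is_coding:
            tally["D"] += 1
            continue
        iv = pred.selected_interval()
        if iv is None:
            tally["D"] += 1
            continue
        touches_left = iv.start == 0
        touches_right = iv.end >= L
        if touches_right and not touches_left:
            tally["A-like"] += 1
        elif touches_left and not touches_right:
            tally["C-like"] += 1
        else:
            tally["B-like"] += 1
    total = sum(tally.values())
    df = pd.DataFrame(
        {
            "class": list(tally),
            "count": list(tally.values()),
            "percent": [100.0 * v / total for v in tally.values()],
        }
    )
    coding = total - tally["D"]
    df.attrs["coding_percent"] = 100.0 * coding / total
    df.attrs["noncoding_percent"] = 100.0 * tally["D"] / total
    return df
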