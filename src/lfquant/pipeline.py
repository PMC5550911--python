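"""Pipeline orchestration: configuration, stage wiring, reporting.

``run_pipeline`` executes synth (or matrix ingest) -> assemble (missingness
filter + log10) -> differential-expression calling -> ordination ->
enrichment, writing every stage's table plus a machine-readable summary
JSON and a log that records the seed and package versions. Stage failures
abort with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemble import (
    QuantMatrix,
    filter_missingness,
    log10_transform,
    read_matrix_tsv,
    write_matrix_tsv,
)
from .destats import DEConfig, call_de
from .enrich import overrepresentation
from .ordination import pca, pearson_cluster
from .quant import QuantParams
from .synth import SynthConfig, generate_annotation_map, generate_intensity_matrix

__all__ = ["PipelineError", "PipelineConfig", "run_pipeline", "ingest_matrix"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration (one YAML file).

    Defaults equal the printed study parameters wherever one exists: 10 ppm
    window, 2-20 s minimum widths, 80 s maximum, S/N 10, noise floor 1000,
    alpha 0.05, five replicates per condition. ``input_matrix`` /
    ``input_conditions`` switch the pipeline from the synthetic generator
    to an external matrix (``column_map`` adapts foreign layouts, see
    :func:`ingest_matrix`).
    """

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    quant: QuantParams = field(default_factory=QuantParams)
    de: DEConfig = field(default_factory=DEConfig)
    input_matrix: str | None = None
    input_conditions: str | None = None
    column_map: dict | None = None
    run_ordination: bool = True
    run_enrichment: bool = True
    annotation_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("synth", SynthConfig), ("quant", QuantParams), ("de", DEConfig)):
            if key in kwargs and kwargs[key] is not None:
                block = dict(kwargs[key])
                if key == "quant" and "min_width_schedule" in block:
                    block["min_width_schedule"] = tuple(block["min_width_schedule"])
                kwargs[key] = sub(**block)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def ingest_matrix(path, column_map: dict, conditions_path=None) -> QuantMatrix:
    """Read an external intensity table into a :class:`QuantMatrix`.

    ``column_map`` must provide ``protein_id`` (the identifier column) and
    the sample columns per condition, e.g.::

        {"protein_id": "Accession",
         "control": ["R18_A", ..., "R18_E"],
         "elevated": ["R22_A", ..., "R22_E"]}

    Malformed numeric cells become missing; the count of such cells is
    logged as a warning.
    """
    for key in ("protein_id", "control", "elevated"):
        if key not in column_map:
            raise PipelineError(f"column_map is missing required key {key!r}")
    df = pd.read_csv(path, sep="\t")
    needed = [column_map["protein_id"], *column_map["control"], *column_map["elevated"]]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise PipelineError(f"input matrix is missing column(s): {absent}")
    df = df.set_index(column_map["protein_id"])
    sample_cols = list(column_map["control"]) + list(column_map["elevated"])
    data = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    n_bad = int((data.isna() & df[sample_cols].notna()).sum().sum())
    if n_bad:
        log.warning("%d malformed numeric cell(s) treated as missing", n_bad)
    data.index.name = "protein"
    from .assemble import CONDITION_CONTROL, CONDITION_ELEVATED

    conditions = pd.Series(
        {**{c: CONDITION_CONTROL for c in column_map["control"]},
         **{c: CONDITION_ELEVATED for c in column_map["elevated"]}}
    )
    return QuantMatrix(data, conditions)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured pipeline; returns the summary dict.

    Writes into ``outdir``: the input matrix and condition map, ground
    truth (synthetic runs), the filtered log10 matrix, the DE result
    table, PCA scores/variance and heatmap orderings, the enrichment
    table, ``summary.json`` and ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lfquant")
    root.addHandler(handler)
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, outdir: Path) -> dict:
    summary: dict = {"seed": cfg.seed, "version": __version__}
    truth = None

    if cfg.input_matrix:
        if cfg.column_map:
            matrix = _stage("ingest")(ingest_matrix)(cfg.input_matrix, cfg.column_map)
        elif cfg.input_conditions:
            matrix = _stage("ingest")(read_matrix_tsv)(cfg.input_matrix, cfg.input_conditions)
        else:
            raise PipelineError("input_matrix requires column_map or input_conditions")
        summary["input"] = str(cfg.input_matrix)
    else:
        synth_cfg = replace(cfg.synth, seed=cfg.seed)
        matrix, truth = _stage("synth")(generate_intensity_matrix)(synth_cfg)
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        summary["input"] = "synthetic"
    write_matrix_tsv(matrix, outdir / "matrix.tsv", outdir / "conditions.tsv")

    spike = cfg.quant.spike_label
    exclude = (spike,) if spike in matrix.data.index else ()

    def _assemble(m):
        filtered, removed = filter_missingness(m)
        return log10_transform(filtered), removed

    logm, removed = _stage("assemble")(_assemble)(matrix)
    write_matrix_tsv(logm, outdir / "matrix_filtered_log10.tsv", outdir / "conditions.tsv")
    summary["n_input_proteins"] = int(len(matrix.data)) - len(exclude)
    summary["n_removed_missingness"] = len(removed)
    summary["n_analyzed_proteins"] = int(len(logm.data)) - len(exclude)

    results, de_meta = _stage("destats")(call_de)(logm, cfg.de, exclude=exclude)
    results.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    summary["de"] = de_meta

    if truth is not None:
        merged = results.merge(truth, on="protein", how="left")
        truly = merged["true_class"] != "null"
        called = merged["call"] != "ns"
        tp = int((truly & called & (np.where(merged["true_log10_fc"] > 0, "up", "down") == merged["call"])).sum())
        summary["recovery"] = {
            "n_true_de_analyzed": int(truly.sum()),
            "true_positives": tp,
            "false_positives": int((~truly & called).sum()),
            "sensitivity": tp / truly.sum() if truly.sum() else float("nan"),
        }

    if cfg.run_ordination:
        de_proteins = list(results.loc[results["call"] != "ns", "protein"])
        scope = "de_only" if len(de_proteins) >= 2 else "all"
        res = _stage("ordination")(pca)(
            logm if not exclude else QuantMatrix(logm.data.drop(list(exclude)), logm.conditions, True),
            scope=scope,
            de_proteins=de_proteins or None,
        )
        res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample")
        pd.DataFrame(
            {"component": res.scores.columns, "variance_pct": res.variance_pct}
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        summary["pca"] = {
            "scope": scope,
            "variance_pct": [round(float(v), 3) for v in res.variance_pct[:4]],
        }
        if len(de_proteins) >= 2:
            sub = QuantMatrix(logm.data.loc[de_proteins], logm.conditions, True)
            order = _stage("ordination")(pearson_cluster)(sub)
            pd.DataFrame({"protein": order.row_order}).to_csv(
                outdir / "heatmap_row_order.tsv", sep="\t", index=False
            )
            pd.DataFrame({"sample": order.col_order}).to_csv(
                outdir / "heatmap_col_order.tsv", sep="\t", index=False
            )

    if cfg.run_enrichment:
        reference = [p for p in logm.data.index if p not in set(exclude)]
        de_proteins = list(results.loc[results["call"] != "ns", "protein"])
        if cfg.annotation_tsv:
            from .enrich import load_annotation_tsv

            ann = load_annotation_tsv(cfg.annotation_tsv)
        else:
            ann = generate_annotation_map(reference, seed=cfg.seed)
        if de_proteins:
            table = _stage("enrich")(overrepresentation)(de_proteins, reference, ann)
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_categories": int(len(table)),
                "n_significant": int(table["significant"].sum()) if len(table) else 0,
            }
        else:
            summary["enrichment"] = {"n_categories": 0, "n_significant": 0}

    summary["config"] = cfg.to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
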