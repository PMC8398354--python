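"""End-to-end QSAR workflow: configuration, orchestration and reporting.

``run_full`` chains every stage — ingest or generate, featurise, curate,
split, descriptor selection, PLS fit, internal/external validation,
prediction, potency binning and applicability-domain checks — persisting
every intermediate table so each number in the run report can be recomputed
from the artifacts alone. Runs are deterministic under a fixed seed, and
the effective configuration (plus its hash) is embedded in the report.

The selection cascade is executed and reported at every run; the fitted
model defaults to the full five-descriptor family (the modelled family),
with ``fit_on_selected`` switching to cascade-driven fitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset, curate, similarity_activity_split
from .descriptors import DescriptorCalculator
from .model import (ActivityBin, PLSActivityModel, bin_activity,
                    flag_outliers, pearson_r2, rmse, validate)
from .selection import select_descriptors
from .synthetic import make_library

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric choice of the workflow in one serialisable record."""

    tc_curation: float = 0.3
    tc_domain: float = 0.5
    activity_corr: float = 0.5
    collinearity: float = 0.7
    outlier_threshold: float = 2.5
    outlier_absolute: bool = True
    bin_edges: tuple[float, float, float] = (5.80, 7.00, 8.00)
    train_fraction: float = 0.8
    seed: int = 0
    sigma: float = 0.0
    n_synthetic: int = 76
    fit_on_selected: bool = False
    n_latent: int | None = None
    log_base: str = "e"
    charge_iterations: int = 8
    hyd_threshold: float = 0.2
    percent_mode: str = "largest_remainder"   # or "round"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(d["bin_edges"])
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bin_edges" in data:
            data = {**data, "bin_edges": tuple(data["bin_edges"])}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("tc_curation", "tc_domain", "activity_corr",
                     "collinearity", "train_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.outlier_threshold < 0 or self.sigma < 0:
            raise ValueError("thresholds must be non-negative")
        if not (self.bin_edges[0] < self.bin_edges[1] < self.bin_edges[2]):
            raise ValueError("bin edges must increase")
        if self.percent_mode not in ("largest_remainder", "round"):
            raise ValueError(f"unknown percent_mode {self.percent_mode!r}")

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def calculator(self) -> DescriptorCalculator:
        base = math.e if self.log_base == "e" else float(self.log_base)
        return DescriptorCalculator(
            log_base=base, charge_iterations=self.charge_iterations,
            hyd_threshold=self.hyd_threshold)


def percentages(counts: dict[str, int], mode: str = "largest_remainder"
                ) -> dict[str, dict[str, float]]:
    """Integer percentage census with a 1-dp companion column.

    ``largest_remainder`` apportions integer percentages so they sum to 100
    (the convention that reproduces published activity censuses); ``round``
    rounds each share independently.
    """
    total = sum(counts.values())
    out: dict[str, dict[str, float]] = {}
    if total == 0:
        return {k: {"count": 0, "pct": 0.0, "pct_int": 0} for k in counts}
    exact = {k: 100.0 * v / total for k, v in counts.items()}
    if mode == "round":
        ints = {k: int(round(p)) for k, p in exact.items()}
    else:
        ints = {k: int(p) for k, p in exact.items()}
        shortfall = 100 - sum(ints.values())
        order = sorted(exact, key=lambda k: exact[k] - ints[k], reverse=True)
        for k in order[:shortfall]:
            ints[k] += 1
    for k in counts:
        out[k] = {"count": counts[k], "pct": round(exact[k], 1),
                  "pct_int": ints[k]}
    return out


@dataclass
class RunReport:
    """Stage-by-stage account of one pipeline run."""

    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    bin_census: dict = field(default_factory=dict)
    domain_census: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_full(config: PipelineConfig, input_path: str | Path | None = None,
             outdir: str | Path = "benzoqsar_run") -> RunReport:
    """Execute the complete workflow; returns the report, persists artifacts.

    With ``input_path`` unset a synthetic benzodiazepine library of
    ``config.n_synthetic`` molecules is generated (noise ``config.sigma``).
    Any stage failure raises with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), config_hash=config.hash())
    stage = "ingest"
    try:
        if input_path is None:
            lib = make_library(config.n_synthetic, seed=config.seed,
                               sigma=config.sigma)
            records = lib.records
            (outdir / "library.manifest.json").write_text(
                json.dumps(lib.manifest, indent=2, sort_keys=True))
        else:
            from .chem import read_records
            records = read_records(input_path)
        dataset = Dataset.from_records(records)
        report.stages["ingest"] = {"n": len(dataset)}

        stage = "featurize"
        dataset.featurize(config.calculator())
        dataset.frame().to_csv(outdir / "featurized.csv", index=False)
        report.stages["featurize"] = {"n": len(dataset)}

        stage = "curate"
        curated, removed = curate(dataset, tc_cutoff=config.tc_curation)
        removed.to_csv(outdir / "curation_removed.csv", index=False)
        for _, row in removed.iterrows():
            report.warnings.append(
                f"curation removed {row['id']} "
                f"(average T_c {row['average_tc']:.3f})")
        report.stages["curate"] = {"n": len(curated),
                                   "removed": len(removed)}

        stage = "split"
        split = similarity_activity_split(
            curated, train_fraction=config.train_fraction, seed=config.seed)
        train, test = curated.subset(split.train_indices), \
            curated.subset(split.test_indices)
        train.frame().to_csv(outdir / "train.csv", index=False)
        test.frame().to_csv(outdir / "test.csv", index=False)
        report.stages["split"] = {"n_train": len(train), "n_test": len(test)}

        stage = "select"
        selected, sel_report = select_descriptors(
            train.descriptors, train.activities,
            activity_corr_min=config.activity_corr,
            collinearity_max=config.collinearity)
        sel_report.mutual_corr.to_csv(outdir / "selection_mutual_corr.csv")
        sel_report.activity_corr.to_csv(
            outdir / "selection_activity_corr.csv", header=["r"])
        report.stages["select"] = {
            "selected": selected,
            "dropped_low_corr": sel_report.dropped_low_corr,
            "dropped_collinear": sel_report.dropped_collinear,
            "fit_on_selected": config.fit_on_selected}
        for name in sel_report.dropped_low_corr + sel_report.dropped_collinear:
            report.warnings.append(f"selection dropped descriptor {name}")

        stage = "fit"
        X_train = (train.descriptors[selected] if config.fit_on_selected
                   else train.descriptors)
        model = PLSActivityModel(n_components=config.n_latent).fit(
            X_train, train.activities)
        model_dict = model.to_dict()
        model_dict.update({"config_hash": config.hash(),
                           "seed": config.seed,
                           "fit_on_selected": config.fit_on_selected})
        (outdir / "model.json").write_text(
            json.dumps(model_dict, indent=2, sort_keys=True))
        fitted_names = (list(model.feature_names_in_)
                        if model.feature_names_in_ is not None else [])
        report.stages["fit"] = {"n_latent": model.n_components_,
                                "descriptors": fitted_names}

        stage = "validate"
        X_test = (test.descriptors[selected] if config.fit_on_selected
                  else test.descriptors)
        vr = validate(model, X_test, test.activities, ids=test.ids,
                      outlier_threshold=config.outlier_threshold)
        vr.rmse_train = rmse(train.activities, model.predict(X_train))
        vr.residuals.to_csv(outdir / "test_residuals.csv", index=False)
        train_outliers = flag_outliers(
            train.ids, train.activities, model.predict(X_train),
            threshold=config.outlier_threshold,
            absolute=config.outlier_absolute)
        report.validation = vr.summary()
        report.validation["rmse_train"] = vr.rmse_train
        report.validation["train_outliers"] = [
            {"id": i, "deviation": d} for i, d in train_outliers]

        stage = "predict"
        X_all = (curated.descriptors[selected] if config.fit_on_selected
                 else curated.descriptors)
        predictions = model.predict(X_all)
        bins = [bin_activity(p, edges=config.bin_edges).value
                for p in predictions]
        from .chem import average_tc
        from .dataset import DomainVerdict
        domain = []
        for fp in curated.fingerprints:   # fingerprints already computed
            avg = average_tc(fp, curated.fingerprints)
            domain.append(DomainVerdict(in_domain=avg >= config.tc_domain,
                                        average_tc=avg,
                                        cutoff=config.tc_domain))
        pred_frame = pd.DataFrame({
            "id": curated.ids,
            "smiles": [r.smiles for r in curated.records],
            "predicted": np.round(predictions, 5),
            "predicted_2dp": np.round(predictions, 2),
            "bin": bins,
            "in_domain": [d.in_domain for d in domain],
            "average_tc": [round(d.average_tc, 4) for d in domain]})
        pred_frame.to_csv(outdir / "predictions.csv", index=False)
        report.stages["predict"] = {"n": len(pred_frame)}

        stage = "census"
        counts = {b.value: bins.count(b.value) for b in ActivityBin}
        report.bin_census = percentages(counts, mode=config.percent_mode)
        in_domain = sum(d.in_domain for d in domain)
        report.domain_census = percentages(
            {"in_domain": in_domain, "out_of_domain": len(domain) - in_domain},
            mode=config.percent_mode)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    return report
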