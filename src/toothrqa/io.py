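"""CSV/TSV formats, run configuration and the staged pipeline driver.

Series travel as long-format CSV (``subject_id,element,day,ratio``),
subjects as a flat CSV, features/scores/loadings as wide CSV, and scan
results as TSV.  Every output file starts with a comment header carrying
the configuration hash and the seed, so a run can be identified from any
of its artifacts.
"""
from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dimred, features, stats
from .errors import FileFormatError, ValidationError
from .rqa import EmbeddingParams
from .synthetic import (
    CohortConfig,
    ElementalTimeSeries,
    SignalParams,
    SubjectRecord,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "read_series_csv",
    "write_series_csv",
    "read_subjects_csv",
    "write_subjects_csv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SERIES_HEADER = ["subject_id", "element", "day", "ratio"]
SUBJECT_HEADER = [
    "subject_id",
    "pair_id",
    "zygosity",
    "sex",
    "gestational_days",
    "birth_weight",
    "diagnosis",
    "iq",
]


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    pathways: list[features.PathwaySpec] = field(
        default_factory=features.default_pathways
    )
    outlier_k: float = 2.0
    outlier_mode: str = "auto"
    alpha: float = 0.05
    output_dir: str = "toothrqa_out"
    seed: int = 0

    def __post_init__(self):
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        for p in self.pathways:
            for el in filter(None, (p.element, p.partner)):
                if el not in self.cohort.elements:
                    raise ValidationError(
                        f"pathway {p.name} references element {el} not present "
                        "in the cohort element list",
                        "pathways",
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["group_sizes"] = {
            k.value: v for k, v in self.cohort.group_sizes.items()
        }
        d["cohort"]["pathway_effects"] = {
            f"{dx.value}:{key}": v
            for (dx, key), v in self.cohort.pathway_effects.items()
        }
        d["cohort"]["elements"] = list(self.cohort.elements)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "pathway_effects" in c:
                c["pathway_effects"] = {
                    tuple(k.split(":", 1)): v for k, v in c["pathway_effects"].items()
                }
            if "signal" in c and isinstance(c["signal"], dict):
                c["signal"] = SignalParams(**c["signal"])
            if "elements" in c:
                c["elements"] = tuple(c["elements"])
            d["cohort"] = CohortConfig(**c)
        if "embedding" in d and isinstance(d["embedding"], dict):
            d["embedding"] = EmbeddingParams(**d["embedding"])
        if "pathways" in d:
            d["pathways"] = [
                p if isinstance(p, features.PathwaySpec) else features.PathwaySpec(**p)
                for p in d["pathways"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header_comment(config: RunConfig | None) -> str:
    if config is None:
        return "# toothrqa\n"
    return f"# toothrqa config={config.config_hash} seed={config.seed}\n"


def write_series_csv(
    series: Iterable[ElementalTimeSeries], path: str | Path,
    config: RunConfig | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config))
        writer = csv.writer(fh)
        writer.writerow(SERIES_HEADER)
        for s in series:
            for t, v in zip(s.times, s.values):
                writer.writerow([s.subject_id, s.element, repr(float(t)), repr(float(v))])


def read_series_csv(path: str | Path) -> list[ElementalTimeSeries]:
    """Parse long-format series CSV, validating as it goes.

    Duplicate (subject, element, day) rows and negative ratios raise a
    ``FileFormatError`` naming the offending 1-based line number.
    """
    grouped: dict[tuple[str, str], list[tuple[float, float]]] = {}
    seen: dict[tuple[str, str, float], int] = {}
    with open(path, newline="") as fh:
        header_seen = False
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                if row != SERIES_HEADER:
                    raise FileFormatError(
                        f"line {lineno}: expected header "
                        f"{','.join(SERIES_HEADER)!r}, got {','.join(row)!r}",
                        line=lineno,
                    )
                header_seen = True
                continue
            if len(row) != 4:
                raise FileFormatError(
                    f"line {lineno}: expected 4 fields, got {len(row)}", line=lineno
                )
            sid, element = row[0], row[1]
            try:
                day, ratio = float(row[2]), float(row[3])
            except ValueError as exc:
                raise FileFormatError(
                    f"line {lineno}: non-numeric day/ratio ({exc})", line=lineno
                ) from None
            if ratio < 0:
                raise FileFormatError(
                    f"line {lineno}: negative ratio {ratio}", line=lineno
                )
            key = (sid, element, day)
            if key in seen:
                raise FileFormatError(
                    f"line {lineno}: duplicate day {day:g} for subject {sid} "
                    f"element {element} (first at line {seen[key]})",
                    line=lineno,
                )
            seen[key] = lineno
            grouped.setdefault((sid, element), []).append((day, ratio))
        if not header_seen:
            raise FileFormatError("empty file: missing header", line=1)
    out = []
    for (sid, element), rows in grouped.items():
        rows.sort()
        days = np.array([r[0] for r in rows])
        vals = np.array([r[1] for r in rows])
        out.append(ElementalTimeSeries(sid, element, days, vals))
    return out


def write_subjects_csv(
    subjects: Sequence[SubjectRecord], path: str | Path,
    config: RunConfig | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config))
        writer = csv.writer(fh)
        writer.writerow(SUBJECT_HEADER)
        for s in subjects:
            writer.writerow(
                [
                    s.subject_id,
                    s.pair_id,
                    s.zygosity.value,
                    s.sex,
                    repr(float(s.gestational_days)),
                    repr(float(s.birth_weight)),
                    s.diagnosis.value,
                    "" if s.iq is None else repr(float(s.iq)),
                ]
            )


def read_subjects_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SUBJECT_HEADER if c not in df.columns]
    if missing:
        raise FileFormatError(f"subject CSV missing column(s): {', '.join(missing)}")
    out = []
    for _, r in df.iterrows():
        iq = r.get("iq")
        out.append(
            SubjectRecord(
                str(r["subject_id"]),
                str(r["pair_id"]),
                r["zygosity"],
                str(r["sex"]),
                float(r["gestational_days"]),
                float(r["birth_weight"]),
                r["diagnosis"],
                None if pd.isna(iq) else float(iq),
            )
        )
    return out


def write_matrix_text(matrix, path: str | Path) -> None:
    """Export a recurrence matrix as a plain-text 0/1 grid (rows =
    matrix rows, no separators)."""
    entries = np.asarray(matrix.entries, dtype=int)
    with open(path, "w") as fh:
        for row in entries:
            fh.write("".join("1" if v else "0" for v in row) + "\n")


def write_features_long(table: pd.DataFrame, path: str | Path) -> None:
    """Export a feature table in long format:
    ``subject_id,pathway,measure,value`` (missing cells skipped)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "pathway", "measure", "value"])
        for sid, row in table.iterrows():
            for col, val in row.items():
                if pd.isna(val):
                    continue
                pathway, _, measure = col.rpartition("_")
                writer.writerow([sid, pathway, measure, repr(float(val))])


def _write_frame(df: pd.DataFrame, path: Path, config: RunConfig, sep=",", index=True):
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        df.to_csv(fh, sep=sep, index=index)


def run_pipeline(
    config: RunConfig,
    stage: str = "run",
    series_path: str | Path | None = None,
    subjects_path: str | Path | None = None,
) -> dict[str, Path]:
    """Simulate (or load) -> features -> scan -> dimred, writing artifacts.

    ``stage``: "run" executes everything from simulation; "features"
    starts from provided series/subject CSVs.  Returns a mapping of
    artifact names to paths.  Identical configs produce identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: list[str] = [f"toothrqa run (config {config.config_hash}, seed {config.seed})"]

    if stage == "run":
        subjects, series = generate_cohort(config.cohort)
        write_subjects_csv(subjects, out / "subjects.csv", config)
        write_series_csv(series, out / "series.csv", config)
        artifacts["subjects"] = out / "subjects.csv"
        artifacts["series"] = out / "series.csv"
        summary.append(
            f"simulated cohort: {len(subjects)} subjects, {len(series)} series"
        )
    elif stage == "features":
        if series_path is None or subjects_path is None:
            raise ValidationError(
                "stage 'features' needs series_path and subjects_path", "stage"
            )
        series = read_series_csv(series_path)
        subjects = read_subjects_csv(subjects_path)
        summary.append(f"loaded cohort: {len(subjects)} subjects, {len(series)} series")
    else:
        raise ValidationError(f"unknown stage {stage!r}", "stage")

    table = features.compute_feature_table(
        series, subjects, config.pathways, config.embedding
    )
    _write_frame(table, out / "feature_table.csv", config)
    artifacts["features"] = out / "feature_table.csv"
    n_missing = int(table.isna().to_numpy().sum())
    summary.append(
        f"feature table: {table.shape[0]} subjects x {table.shape[1]} features "
        f"({n_missing} missing cells)"
    )
    if table.attrs.get("missing_log"):
        miss = pd.DataFrame(
            table.attrs["missing_log"], columns=["subject_id", "pathway", "cause"]
        )
        _write_frame(miss, out / "missing_cells.csv", config, index=False)
        artifacts["missing_cells"] = out / "missing_cells.csv"

    results = stats.run_feature_scan(
        table, subjects, config.outlier_k, config.outlier_mode
    )
    scan = stats.scan_frame(results)
    _write_frame(scan, out / "scan_results.tsv", config, sep="\t", index=False)
    artifacts["scan"] = out / "scan_results.tsv"
    n_sig = int((scan["p_fdr"] <= config.alpha).sum())
    summary.append(
        f"mixed-model scan: {len(scan)} features, "
        f"{n_sig} ADHD effects with FDR p <= {config.alpha:g}"
    )

    pca = dimred.pca_fit(table)
    eig = pd.DataFrame(
        {
            "component": [f"PC{i}" for i in range(1, len(pca.eigenvalues) + 1)],
            "eigenvalue": pca.eigenvalues,
            "variance_share": pca.variance_share,
            "retained": [i in pca.retained for i in range(1, len(pca.eigenvalues) + 1)],
        }
    )
    _write_frame(eig, out / "pca_eigenvalues.csv", config, index=False)
    _write_frame(pca.scores, out / "pca_scores.csv", config)
    _write_frame(pca.loadings, out / "pca_loadings.csv", config)
    artifacts["pca_eigenvalues"] = out / "pca_eigenvalues.csv"
    artifacts["pca_scores"] = out / "pca_scores.csv"
    artifacts["pca_loadings"] = out / "pca_loadings.csv"
    share = float(pca.variance_share[: len(pca.retained)].sum()) * 100
    summary.append(
        f"PCA: retained {len(pca.retained)} components "
        f"({share:.2f}% of variance, all eigenvalues > 1)"
    )
    comp_names = [f"PC{i}" for i in pca.retained]
    if comp_names:
        tests = dimred.component_group_tests(pca.scores, subjects, comp_names)
        _write_frame(tests, out / "pca_group_tests.tsv", config, sep="\t", index=False)
        artifacts["pca_group_tests"] = out / "pca_group_tests.tsv"

    lda = dimred.lda_fit(table, subjects)
    _write_frame(lda.scores, out / "lda_scores.csv", config)
    _write_frame(lda.standardized_loadings, out / "lda_loadings.csv", config)
    _write_frame(lda.class_means, out / "lda_class_means.csv", config)
    artifacts["lda_scores"] = out / "lda_scores.csv"
    artifacts["lda_loadings"] = out / "lda_loadings.csv"
    artifacts["lda_class_means"] = out / "lda_class_means.csv"
    acc = float((dimred.reclassify(lda) == _dx_series(subjects, lda)).mean())
    summary.append(
        f"LDA: {lda.axis_count} axes, {len(lda.excluded_subjects)} subjects "
        f"excluded, in-sample nearest-mean agreement {acc:.2f}"
    )

    config.to_yaml(out / "config.yaml")
    (out / "summary.txt").write_text(_header_comment(config) + "\n".join(summary) + "\n")
    artifacts["summary"] = out / "summary.txt"
    logger.info("pipeline complete: %s", out)
    return artifacts


def _dx_series(subjects: Sequence[SubjectRecord], lda: dimred.LDAResult) -> pd.Series:
    dx = {s.subject_id: s.diagnosis.value for s in subjects}
    return pd.Series([dx[s] for s in lda.scores.index], index=lda.scores.index)
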