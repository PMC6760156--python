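"""Cohort-level feature extraction: subjects x (pathway, measure) table.

The default pathway set mirrors the analysis design of eight single
elements (Zn, Cu, Pb, Co, V, Li, Sn, Mn) and seven zinc-centered
cross-recurrences (Zn with Cu, Pb, Co, V, Li, Sn, Ca), each contributing
the four recurrence measures DET, MDL, ENTR and RT — 60 columns in all.
Zinc-centered pairs only: zinc is the hypothesised central regulator, so
no other cross pairs are formed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import rqa
from .errors import ToothRQAError, ValidationError
from .rqa import EmbeddingParams
from .synthetic import ElementalTimeSeries, SubjectRecord

__all__ = [
    "PathwaySpec",
    "MEASURES",
    "default_pathways",
    "compute_feature_table",
]

logger = logging.getLogger(__name__)

MEASURES = ("DET", "MDL", "ENTR", "RT")

_DEFAULT_SINGLES = ("Zn", "Cu", "Pb", "Co", "V", "Li", "Sn", "Mn")
_DEFAULT_PARTNERS = ("Cu", "Pb", "Co", "V", "Li", "Sn", "Ca")


@dataclass(frozen=True)
class PathwaySpec:
    """A single-element pathway or a zinc-centered cross-recurrence."""

    kind: str  # "SINGLE" or "ZINC_PAIR"
    element: str
    partner: str | None = None

    def __post_init__(self):
        if self.kind not in ("SINGLE", "ZINC_PAIR"):
            raise ValidationError(f"unknown pathway kind {self.kind!r}", "kind")
        if self.kind == "ZINC_PAIR":
            if self.partner is None:
                raise ValidationError("ZINC_PAIR needs a partner element", "partner")
            if "Zn" not in (self.element, self.partner):
                raise ValidationError(
                    "a ZINC_PAIR pathway must include zinc", "element"
                )
        elif self.partner is not None:
            raise ValidationError("SINGLE pathways take no partner", "partner")

    @property
    def name(self) -> str:
        if self.kind == "SINGLE":
            return self.element
        return f"{self.element}-{self.partner}"


def default_pathways() -> list[PathwaySpec]:
    """8 single-element + 7 zinc-pair pathways (60 features with the four
    measures)."""
    paths = [PathwaySpec("SINGLE", el) for el in _DEFAULT_SINGLES]
    paths += [PathwaySpec("ZINC_PAIR", "Zn", p) for p in _DEFAULT_PARTNERS]
    return paths


def _index_series(
    series: Iterable[ElementalTimeSeries],
) -> dict[tuple[str, str], ElementalTimeSeries]:
    out: dict[tuple[str, str], ElementalTimeSeries] = {}
    for s in series:
        out[(s.subject_id, s.element)] = s
    return out


def _series_features(
    smap, subject_id: str, pathway: PathwaySpec, params: EmbeddingParams,
    min_embedded: int,
):
    """Features for one cell group, or (None, reason) when missing."""
    if pathway.kind == "SINGLE":
        s = smap.get((subject_id, pathway.element))
        if s is None:
            return None, f"no {pathway.element} series"
        if len(s) - (params.dimension - 1) * params.delay < min_embedded:
            return None, f"{pathway.element} series too short"
        feats = rqa.rqa_features_from_values(s.values, params)
    else:
        a = smap.get((subject_id, "Zn"))
        b = smap.get((subject_id, pathway.partner))
        if a is None or b is None:
            missing = "Zn" if a is None else pathway.partner
            return None, f"no {missing} series"
        if min(len(a), len(b)) - (params.dimension - 1) * params.delay < min_embedded:
            return None, f"{pathway.name} series too short"
        feats = rqa.rqa_features(rqa.cross_recurrence_matrix(a, b, params))
    return feats, None


def compute_feature_table(
    series: Iterable[ElementalTimeSeries],
    subjects: Sequence[SubjectRecord],
    pathways: Sequence[PathwaySpec] | None = None,
    params: EmbeddingParams | None = None,
    min_embedded: int = rqa.MIN_EMBEDDED_POINTS,
) -> pd.DataFrame:
    """Recurrence features for every subject and pathway.

    Returns a DataFrame indexed by subject_id with one column per
    (pathway, measure), named ``<pathway>_<measure>`` (e.g. ``Zn-Cu_ENTR``).
    Missing series, short series and degenerate trajectories produce
    missing cells (NaN), never errors; every missing cell and its cause is
    logged and collected in ``table.attrs["missing_log"]``.
    """
    if pathways is None:
        pathways = default_pathways()
    if len(pathways) == 0:
        raise ValidationError("pathway list must not be empty", "pathways")
    if params is None:
        params = EmbeddingParams()
    smap = _index_series(series)

    columns = [f"{p.name}_{m}" for p in pathways for m in MEASURES]
    table = pd.DataFrame(
        np.nan, index=[s.subject_id for s in subjects], columns=columns
    )
    table.index.name = "subject_id"
    missing_log: list[tuple[str, str, str]] = []

    for subj in subjects:
        for pathway in pathways:
            try:
                feats, reason = _series_features(
                    smap, subj.subject_id, pathway, params, min_embedded
                )
            except ToothRQAError as exc:
                feats, reason = None, str(exc)
            if feats is None:
                missing_log.append((subj.subject_id, pathway.name, reason))
                logger.info(
                    "missing cell: subject=%s pathway=%s (%s)",
                    subj.subject_id, pathway.name, reason,
                )
                continue
            fd = feats.as_dict()
            for m in MEASURES:
                v = fd[m]
                if v is None:
                    missing_log.append(
                        (subj.subject_id, f"{pathway.name}_{m}", "empty histogram")
                    )
                else:
                    table.loc[subj.subject_id, f"{pathway.name}_{m}"] = v
    table.attrs["missing_log"] = missing_log
    return table
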