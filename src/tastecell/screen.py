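"""Tissue-specificity expression screen.

Candidate genes for taste-papilla-specific function are selected from a
per-gene table of RPKM values in circumvallate papillae (CvP) versus the
surrounding non-taste epithelium (Epi) by two strict thresholds: CvP RPKM
greater than 10, and a CvP/Epi ratio greater than 3.  A gene absent from the
epithelium (Epi = 0) passes whenever its CvP expression does, its ratio being
reported as infinite.  Family flagging then intersects the passing set with a
gene family of interest (e.g. the eight-member Tmc family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .biophys import InvalidInputError

__all__ = [
    "ExpressionRecord",
    "ScreenResult",
    "screen_candidates",
    "flag_family",
    "read_expression_csv",
]

DEFAULT_MIN_CVP = 10.0
DEFAULT_MIN_RATIO = 3.0


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression: RPKM in taste papillae (CvP) and epithelium (Epi)."""

    gene_id: str
    rpkm_cvp: float
    rpkm_epi: float

    def __post_init__(self) -> None:
        for name in ("rpkm_cvp", "rpkm_epi"):
            x = getattr(self, name)
            if not (math.isfinite(x) and x >= 0):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {x!r}")

    @property
    def ratio(self) -> float:
        """CvP/Epi ratio; +inf when the gene is absent from the epithelium."""
        return math.inf if self.rpkm_epi == 0 else self.rpkm_cvp / self.rpkm_epi


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the tissue-specificity screen."""

    passing: tuple  # gene ids, input order preserved
    min_cvp: float
    min_ratio: float
    ratios: dict  # gene_id -> CvP/Epi ratio (math.inf where Epi = 0)


def _as_records(table) -> list:
    if isinstance(table, pd.DataFrame):
        return [ExpressionRecord(str(r.gene_id), float(r.rpkm_cvp), float(r.rpkm_epi))
                for r in table.itertuples(index=False)]
    return list(table)


def screen_candidates(table: Sequence[ExpressionRecord] | pd.DataFrame,
                      min_cvp: float = DEFAULT_MIN_CVP,
                      min_ratio: float = DEFAULT_MIN_RATIO) -> ScreenResult:
    """Apply the two-threshold specificity filter.

    Both criteria are strict inequalities: rpkm_cvp > min_cvp and
    rpkm_cvp/rpkm_epi > min_ratio (Epi = 0 giving an infinite ratio).  Gene
    order is preserved; duplicate gene ids are rejected.
    """
    records = _as_records(table)
    seen = set()
    for r in records:
        if r.gene_id in seen:
            raise InvalidInputError(f"duplicate gene id {r.gene_id!r}")
        seen.add(r.gene_id)
    passing = tuple(r.gene_id for r in records
                    if r.rpkm_cvp > min_cvp and r.ratio > min_ratio)
    return ScreenResult(passing=passing, min_cvp=min_cvp, min_ratio=min_ratio,
                        ratios={r.gene_id: r.ratio for r in records})


def flag_family(result: ScreenResult, family: str | Iterable[str]) -> tuple:
    """Members of a gene family among the screen's passing genes.

    ``family`` is either a gene-id prefix (e.g. ``"Tmc"``) or an explicit
    iterable of gene ids; the passing order is preserved.
    """
    if isinstance(family, str):
        return tuple(g for g in result.passing if g.startswith(family))
    members = set(family)
    return tuple(g for g in result.passing if g in members)


def read_expression_csv(path) -> list:
    """Read a (gene_id, rpkm_cvp, rpkm_epi) CSV into expression records."""
    df = pd.read_csv(path)
    missing = {"gene_id", "rpkm_cvp", "rpkm_epi"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"expression CSV missing columns: {sorted(missing)}")
    return _as_records(df)
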