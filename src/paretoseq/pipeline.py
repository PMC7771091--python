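"""In-memory orchestration of the matching -> integration -> ranking chain.

The CLI wraps these functions around files; tests and scripted analyses
call them directly on in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import integration, matching
from .chip import MarkSpec, RegionCounts
from .errors import ValidationError
from .integration import DiffResult, ZScoreTable
from .matching import MatchedSignal
from .pareto import ParetoRanking, assign_fronts
from .rnaseq import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["IntegrationParams", "match_all", "integrate", "prioritize", "run_pipeline"]


@dataclass
class IntegrationParams:
    """Knobs of the differential stage, with their defaults."""

    condition_a: str = "A"
    condition_b: str = "B"
    pseudocount: float = integration.DEFAULT_PSEUDOCOUNT
    se_min: float = integration.DEFAULT_SE_MIN
    shrinkage: bool = True
    prior_scale: object = "auto"
    allow_pseudo_reference: bool = False


def match_all(
    region_counts: dict[str, RegionCounts],
    marks: list[MarkSpec],
    strategy: str = "highest",
) -> dict[str, MatchedSignal]:
    """Match every mark's region counts to gene level (body marks pass through)."""
    by_name = {m.mark_name: m for m in marks}
    unknown = set(region_counts) - set(by_name)
    if unknown:
        raise ValidationError(f"region counts for marks not in the design: {sorted(unknown)}")
    return {name: matching.match(rc, strategy=strategy) for name, rc in region_counts.items()}


def _matched_to_counts(ms: MatchedSignal, condition: dict[str, str]) -> CountMatrix:
    # matched values can be real-valued (weighted.mean); round for the count model
    rounded = ms.values.round().astype("int64")
    return CountMatrix(rounded, {s: condition[s] for s in rounded.columns})


def _diff_one(cm: CountMatrix, layer: str, params: IntegrationParams) -> DiffResult:
    d = integration.logfc_se(
        cm,
        params.condition_a,
        params.condition_b,
        pseudocount=params.pseudocount,
        se_min=params.se_min,
        layer=layer,
        allow_pseudo_reference=params.allow_pseudo_reference,
    )
    if params.shrinkage:
        d = integration.shrink_logfc(d, prior_scale=params.prior_scale)
    return d


def integrate(
    rna: CountMatrix,
    matched: dict[str, MatchedSignal],
    directions: dict[str, str],
    params: IntegrationParams | None = None,
) -> tuple[dict[str, DiffResult], ZScoreTable]:
    """Per-layer (logfc, se) estimation, optional shrinkage, and Z scores.

    Returns the per-layer differential tables (``RNA`` plus one per mark)
    and the combined gene x mark Z-score table.
    """
    params = params or IntegrationParams()
    if not matched:
        raise ValidationError("integrate: no matched ChIP layers supplied")
    diffs = {"RNA": _diff_one(rna, "RNA", params)}
    for name, ms in matched.items():
        diffs[name] = _diff_one(_matched_to_counts(ms, rna.condition), name, params)
    zt = integration.z_scores(
        diffs["RNA"], {n: d for n, d in diffs.items() if n != "RNA"}, directions
    )
    return diffs, zt


def prioritize(zt: ZScoreTable) -> ParetoRanking:
    """Pareto-front ranking of the Z-score table."""
    return assign_fronts(zt)


def run_pipeline(
    rna: CountMatrix,
    region_counts: dict[str, RegionCounts],
    marks: list[MarkSpec],
    strategy: str = "highest",
    params: IntegrationParams | None = None,
) -> tuple[dict[str, MatchedSignal], dict[str, DiffResult], ZScoreTable, ParetoRanking]:
    """Full chain: match, integrate, prioritize."""
    matched = match_all(region_counts, marks, strategy=strategy)
    directions = {m.mark_name: m.direction for m in marks if m.mark_name in matched}
    diffs, zt = integrate(rna, matched, directions, params)
    return matched, diffs, zt, prioritize(zt)
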