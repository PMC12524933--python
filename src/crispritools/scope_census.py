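"""Operon polar-effect scope and PAM-constraint targetability census.

A dCas9 roadblock inside an ORF stops transcription elongation, so every
gene downstream of the target in the same transcription unit is silenced
with it, while upstream genes are unaffected. :func:`knockdown_scope`
predicts that footprint from operon annotation.

:func:`targetability_census` asks, for a set of features (typically
sRNAs, which are often too short or PAM-poor), whether at least one
guide exists under the strand/PAM rules. PAM availability alone is the
default criterion — the genome-uniqueness filter is an explicit opt-in —
because PAM constraints, not off-target collisions, are what limit sRNA
targeting. Both protospacer and PAM must lie inside the feature, so the
minimum targetable length is ``spacer_len + 3`` (23 nt by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from crispritools.genome_io import Feature, GenomeIOError, GenomeRecord
from crispritools.guide_design import (
    DesignParams,
    enumerate_candidates,
    filter_unique,
)


@dataclass(frozen=True)
class KnockdownScope:
    """Predicted polar silencing footprint of one guide within its operon."""

    target_feature_id: str
    operon_id: str
    silenced: tuple[str, ...]
    unaffected_upstream: tuple[str, ...]


def knockdown_scope(target_feature: Feature, features: list[Feature]) -> KnockdownScope:
    """Silenced = target plus all co-operonic genes downstream of it.

    Downstream means larger ``operon_index`` (transcription order);
    genes upstream of the target are reported unaffected. Mixed strands
    within one operon are an annotation error.
    """
    members = [f for f in features if f.operon_id == target_feature.operon_id]
    if target_feature.id not in {m.id for m in members}:
        members.append(target_feature)
    if len({m.strand for m in members}) > 1:
        raise GenomeIOError(
            f"operon {target_feature.operon_id!r}: members on mixed strands"
        )
    members.sort(key=lambda m: m.operon_index)
    t = target_feature.operon_index
    return KnockdownScope(
        target_feature_id=target_feature.id,
        operon_id=target_feature.operon_id,
        silenced=tuple(m.id for m in members if m.operon_index >= t),
        unaffected_upstream=tuple(m.id for m in members if m.operon_index < t),
    )


@dataclass
class FeatureVerdict:
    targetable: bool
    n_candidates: int
    best_dist5: int | None


@dataclass
class CensusResult:
    """Per-feature targetability verdicts plus aggregate counts."""

    per_feature: dict[str, FeatureVerdict] = field(default_factory=dict)

    @property
    def n_targetable(self) -> int:
        return sum(1 for v in self.per_feature.values() if v.targetable)

    @property
    def n_total(self) -> int:
        return len(self.per_feature)

    def summary_json(self) -> str:
        return json.dumps(
            {"n_targetable": self.n_targetable, "n_total": self.n_total}
        )


def targetability_census(
    features: list[Feature],
    genome: list[GenomeRecord],
    params: DesignParams = DesignParams(),
    apply_uniqueness: bool = False,
) -> CensusResult:
    """Count which features admit at least one guide under the PAM rules.

    Deterministic given inputs; features too short for a protospacer+PAM
    footprint are simply untargetable. With ``apply_uniqueness=True``
    only genome-unique candidates count.
    """
    result = CensusResult()
    for feat in features:
        cands = enumerate_candidates(feat, genome, params)
        if apply_uniqueness and cands:
            strict = DesignParams(
                **{**params.__dict__, "require_unique": True}
            )
            cands, _ = filter_unique(cands, genome, strict)
        result.per_feature[feat.id] = FeatureVerdict(
            targetable=len(cands) >= 1,
            n_candidates=len(cands),
            best_dist5=min((c.dist5 for c in cands), default=None),
        )
    return result


def census_to_frame(result: CensusResult, features: list[Feature]) -> pd.DataFrame:
    by_id = {f.id: f for f in features}
    rows = []
    for fid, v in result.per_feature.items():
        f = by_id[fid]
        rows.append(
            {
                "feature_id": fid,
                "ftype": f.ftype,
                "length": len(f),
                "targetable": v.targetable,
                "n_candidates": v.n_candidates,
                "best_dist5": v.best_dist5 if v.best_dist5 is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "ftype", "length", "targetable", "n_candidates", "best_dist5"],
    )


def write_census_tsv(result: CensusResult, features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# crispritools targetability census; length in nt; "
            "best_dist5 = nt from feature 5' end (0-based)\n"
        )
        census_to_frame(result, features).to_csv(fh, sep="\t", index=False)
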