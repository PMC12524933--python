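"""CRISPRi guide candidate enumeration, screening, validation and ranking.

The design rules implemented here are the classic bacterial CRISPRi
criteria for silencing within an ORF:

* the sgRNA base-pairs with the **non-template** (sense) strand of the
  target gene, so the protospacer and its 5'-NGG-3' PAM lie on the
  template strand — operationally, the gene's sense sequence is scanned
  for ``CCN`` and the 20 nt downstream are reverse-complemented into the
  spacer;
* genome-wide uniqueness is screened with an exact-match **specificity
  pattern**: the 12-nt PAM-proximal seed of the spacer plus the GG of
  the PAM (14 informative nt, the PAM's N position a wildcard); guides
  with more than one binding site are discarded;
* pairing validity requires a contiguous matched run of at least 12 bp
  from the PAM-proximal end, which subsumes perfect complementarity over
  the 7 PAM-adjacent nucleotides;
* among surviving guides the one closest to the 5' end of the coding
  sequence is ranked first;
* a seed GC fraction below 0.40 raises a low-GC warning flag (weaker
  silencing expected), but is not a filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from crispritools.genome_io import (
    Feature,
    GenomeRecord,
    feature_sequence,
    revcomp,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignParams:
    """Tunable design-rule parameters (defaults follow the NGG/dCas9 rules)."""

    spacer_len: int = 20
    seed_len: int = 12
    exact_core_len: int = 7
    min_pairing_run: int = 12
    pam: str = "NGG"
    gc_warn_below: float = 0.40
    require_unique: bool = True
    strand_rule: str = "non_template"  # non_template | template | both

    def __post_init__(self) -> None:
        if not (
            self.exact_core_len
            <= self.min_pairing_run
            <= self.seed_len
            <= self.spacer_len
        ):
            raise ValueError(
                "need exact_core_len <= min_pairing_run <= seed_len <= spacer_len"
            )
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if self.strand_rule not in ("non_template", "template", "both"):
            raise ValueError(f"unknown strand_rule {self.strand_rule!r}")

    @property
    def site_len(self) -> int:
        """Protospacer + PAM footprint in nt."""
        return self.spacer_len + len(self.pam)


@dataclass
class GuideCandidate:
    """A candidate guide: spacer + PAM + coordinates + screening metrics.

    ``spacer`` is written 5'->3' and is identical to the protospacer on
    the PAM-bearing strand. ``seed`` is the PAM-proximal ``seed_len`` nt
    (the 3' end of the spacer). ``dist5`` is measured in feature
    orientation from the feature's 5' end to the start of the
    protospacer+PAM footprint. ``offtarget_count`` and ``rank`` stay -1
    until screening/ranking.
    """

    feature_id: str
    record_id: str
    spacer: str
    pam: str
    proto_start: int
    proto_end: int
    pam_strand: str
    seed: str
    seed_gc: float
    dist5: int
    offtarget_count: int = -1
    rank: int = -1
    low_gc_flag: bool = False
    targets_template: bool = False


@dataclass(frozen=True)
class OfftargetHit:
    """One genomic occurrence of a guide's specificity pattern."""

    record_id: str
    start: int
    end: int
    strand: str
    matched_text: str


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _candidate_from_sense(
    feature: Feature,
    sense: str,
    i: int,
    params: DesignParams,
    template: bool,
) -> GuideCandidate | None:
    """Build a candidate from a scan hit at sense offset ``i``.

    Non-template rule: ``sense[i:i+3]`` is CCN, the spacer is the
    reverse complement of the following ``spacer_len`` nt; the
    protospacer+PAM sit on the strand opposite the feature.
    Template rule: ``sense[i:i+spacer_len]`` is the spacer itself with
    the PAM directly 3' of it on the sense strand.
    """
    L = params.spacer_len
    if not template:
        window = sense[i : i + 3 + L]
        spacer = revcomp(window[3:])
        pam = revcomp(window[:3])
        if feature.strand == "+":
            proto_start = feature.start + i + 3
            proto_end = proto_start + L
            pam_strand = "-"
        else:
            proto_end = feature.end - i - 3
            proto_start = proto_end - L
            pam_strand = "+"
    else:
        window = sense[i : i + L + 3]
        spacer = window[:L]
        pam = window[L:]
        if feature.strand == "+":
            proto_start = feature.start + i
            proto_end = proto_start + L
            pam_strand = "+"
        else:
            proto_end = feature.end - i
            proto_start = proto_end - L
            pam_strand = "-"
    if "N" in spacer or "N" in pam:
        return None
    seed = spacer[-params.seed_len :]
    return GuideCandidate(
        feature_id=feature.id,
        record_id=feature.record_id,
        spacer=spacer,
        pam=pam,
        proto_start=proto_start,
        proto_end=proto_end,
        pam_strand=pam_strand,
        seed=seed,
        seed_gc=gc_fraction(seed),
        dist5=i,
        targets_template=template,
    )


def enumerate_candidates(
    feature: Feature,
    genome: list[GenomeRecord],
    params: DesignParams = DesignParams(),
) -> list[GuideCandidate]:
    """Enumerate all guide candidates inside a feature.

    Both protospacer and PAM must lie entirely within the feature
    interval, so features shorter than ``spacer_len + 3`` nt yield no
    candidates. Candidates with N anywhere in spacer or PAM are dropped.
    Returned in ascending ``dist5`` order; counts and ranks are unset.
    """
    sense = feature_sequence(feature, genome)
    if len(sense) < params.site_len:
        logger.info(
            "feature %s (%d nt) shorter than %d nt: no candidates",
            feature.id, len(sense), params.site_len,
        )
        return []
    out: list[GuideCandidate] = []
    scan_non_template = params.strand_rule in ("non_template", "both")
    scan_template = params.strand_rule in ("template", "both")
    for i in range(len(sense) - params.site_len + 1):
        if scan_non_template and sense[i : i + 2] == "CC":
            cand = _candidate_from_sense(feature, sense, i, params, template=False)
            if cand is not None:
                out.append(cand)
        if scan_template and sense[i + params.spacer_len + 1 : i + params.spacer_len + 3] == "GG":
            cand = _candidate_from_sense(feature, sense, i, params, template=True)
            if cand is not None:
                out.append(cand)
    return out


def specificity_pattern(candidate: GuideCandidate, params: DesignParams = DesignParams()) -> str:
    """Uniqueness-search pattern: seed + N + GG, the PAM's N a wildcard.

    The informative (non-wildcard) portion is ``seed_len + 2`` nt long
    (14 under defaults: the 12-nt seed plus the GG of the PAM).
    """
    return candidate.seed + "N" + params.pam[1:]


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # Wildcard N in the pattern matches any unambiguous base; a genomic
    # N never matches any pattern position.
    return re.compile("(?=(" + pattern.replace("N", "[ACGT]") + "))")


def _scan_record(
    record: GenomeRecord, pattern: str, plen: int
) -> list[tuple[int, str]]:
    """Forward-strand occurrences of pattern as (start, matched_text).

    For circular records the scan wraps across the origin; wrapped hits
    report their (linear) start position near the end of the sequence.
    """
    seq = record.seq
    if record.circular and len(seq) >= plen:
        search_space = seq + seq[: plen - 1]
        limit = len(seq)
    else:
        search_space = seq
        limit = len(seq) - plen + 1
    rx = _pattern_regex(pattern)
    return [
        (m.start(), m.group(1))
        for m in rx.finditer(search_space)
        if m.start() < limit
    ]


def count_binding_sites(
    candidate: GuideCandidate,
    genome: list[GenomeRecord],
    params: DesignParams = DesignParams(),
) -> tuple[int, list[OfftargetHit]]:
    """Count genome-wide occurrences of the specificity pattern.

    Exact matching of seed + N + GG on both strands of every record
    (wrapping the origin only for circular records). A candidate taken
    from the genome always scores at least 1 (its own site).
    """
    pattern = specificity_pattern(candidate, params)
    plen = len(pattern)
    hits: list[OfftargetHit] = []
    rc_pattern = revcomp(pattern)
    for record in genome:
        for start, text in _scan_record(record, pattern, plen):
            hits.append(
                OfftargetHit(record.id, start, start + plen, "+", text)
            )
        for start, text in _scan_record(record, rc_pattern, plen):
            hits.append(
                OfftargetHit(record.id, start, start + plen, "-", revcomp(text))
            )
    return len(hits), hits


def filter_unique(
    candidates: list[GuideCandidate],
    genome: list[GenomeRecord],
    params: DesignParams = DesignParams(),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Partition candidates into genome-unique (kept) and multi-site.

    Every candidate's ``offtarget_count`` is annotated. With
    ``require_unique=False`` nothing is discarded; counts are still
    annotated for reporting.
    """
    kept: list[GuideCandidate] = []
    discarded: list[GuideCandidate] = []
    for cand in candidates:
        count, _hits = count_binding_sites(cand, genome, params)
        cand.offtarget_count = count
        if count == 1 or not params.require_unique:
            kept.append(cand)
        else:
            discarded.append(cand)
    return kept, discarded


@dataclass(frozen=True)
class PairingReport:
    """Diagnostics from :func:`validate_pairing`.

    ``run`` is the contiguous matched length from the PAM-proximal end;
    ``mismatches`` are 1-based positions counted from the PAM.
    """

    passed: bool
    run: int
    mismatches: tuple[int, ...]


def validate_pairing(
    spacer: str, site_seq: str, params: DesignParams = DesignParams()
) -> PairingReport:
    """Check whether a spacer still pairs productively with a site.

    The site passes when the contiguous run of matching bases starting
    from the PAM-proximal end (the 3' end of the spacer) reaches
    ``min_pairing_run`` (12 by default). Because the run is contiguous,
    this subsumes the requirement of perfect complementarity over the
    7 PAM-adjacent nucleotides. The PAM is checked separately by callers.
    """
    if len(spacer) != len(site_seq):
        raise ValueError(
            f"spacer ({len(spacer)} nt) and site ({len(site_seq)} nt) differ in length"
        )
    n = len(spacer)
    mismatches = tuple(
        n - i for i in range(n - 1, -1, -1) if spacer[i] != site_seq[i]
    )
    run = 0
    for i in range(n - 1, -1, -1):
        if spacer[i] != site_seq[i]:
            break
        run += 1
    return PairingReport(passed=run >= params.min_pairing_run, run=run, mismatches=mismatches)


def rank_candidates(
    candidates: list[GuideCandidate], params: DesignParams = DesignParams()
) -> list[GuideCandidate]:
    """Order candidates by 5'-proximity and assign ranks.

    Ascending ``dist5`` (closest to the start codon first); ties broken
    deterministically by (record_id, proto_start, spacer). Sets
    ``low_gc_flag`` when the seed GC fraction falls below
    ``gc_warn_below`` and assigns 1-based ``rank``.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (c.dist5, c.record_id, c.proto_start, c.spacer),
    )
    for r, cand in enumerate(ordered, start=1):
        cand.rank = r
        cand.low_gc_flag = cand.seed_gc < params.gc_warn_below
    return ordered


def design_guides(
    feature: Feature,
    genome: list[GenomeRecord],
    params: DesignParams = DesignParams(),
) -> tuple[list[GuideCandidate], list[GuideCandidate]]:
    """Full per-gene workflow: enumerate, uniqueness-screen, rank.

    Returns (ranked kept candidates, discarded multi-site candidates).
    """
    candidates = enumerate_candidates(feature, genome, params)
    kept, discarded = filter_unique(candidates, genome, params)
    return rank_candidates(kept, params), discarded


# ---------------------------------------------------------------------------
# report writers

_TSV_COLUMNS = [
    "feature_id", "spacer", "pam", "record", "proto_start", "proto_end",
    "pam_strand", "dist5", "seed", "seed_gc", "offtarget_count",
    "low_gc_flag", "rank",
]


def guides_to_frame(candidates: Iterable[GuideCandidate]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": c.feature_id,
            "spacer": c.spacer,
            "pam": c.pam,
            "record": c.record_id,
            "proto_start": c.proto_start,
            "proto_end": c.proto_end,
            "pam_strand": c.pam_strand,
            "dist5": c.dist5,
            "seed": c.seed,
            "seed_gc": round(c.seed_gc, 4),
            "offtarget_count": c.offtarget_count,
            "low_gc_flag": c.low_gc_flag,
            "rank": c.rank,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_guide_tsv(candidates: Iterable[GuideCandidate], path) -> None:
    """Guide table as TSV with a commented convention header."""
    with open(path, "w") as fh:
        fh.write(
            "# crispritools guide table; proto_start/proto_end 0-based half-open; "
            "dist5 = nt from feature 5' end to protospacer+PAM footprint; "
            "seed = PAM-proximal end of spacer\n"
        )
        guides_to_frame(candidates).to_csv(fh, sep="\t", index=False)


def write_guide_bed(candidates: Iterable[GuideCandidate], path) -> None:
    """Guide protospacer coordinates as BED6 (name=feature|rank, score=offtargets)."""
    with open(path, "w") as fh:
        for c in candidates:
            name = f"{c.feature_id}|{c.rank}"
            fh.write(
                f"{c.record_id}\t{c.proto_start}\t{c.proto_end}\t{name}"
                f"\t{max(c.offtarget_count, 0)}\t{c.pam_strand}\n"
            )
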