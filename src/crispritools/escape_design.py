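"""Synonymous escape-allele design.

A CRISPRi knockdown of one gene in an operon is polar, so
complementation needs a plasmid copy of the target that the resident
sgRNA cannot silence. The standard trick is to recode the protospacer
region with synonymous codon substitutions: the protein is unchanged,
but guide pairing (or the PAM itself) is broken. Changing two codons in
the 12-bp PAM-proximal seed is the recommended default; a single codon
change within the 7-nt PAM-adjacent core can suffice (a lone proline
codon swap has been shown to fully relieve silencing), so a
``min_codon_changes=1`` mode is supported.

All work happens in CDS sense coordinates, so plus- and minus-strand
features behave identically. The start codon is never mutated; the stop
codon has no synonymous alternatives in this scheme and is left alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

from crispritools.genome_io import (
    Feature,
    GenomeIOError,
    revcomp,
    synonymous_codons,
    translate,
)
from crispritools.guide_design import (
    DesignParams,
    GuideCandidate,
    PairingReport,
    validate_pairing,
)


class EscapeDesignError(ValueError):
    pass


@dataclass(frozen=True)
class GuideRegion:
    """Sense-coordinate intervals of a guide's footprint within its CDS.

    All half-open intervals in CDS sense coordinates. ``pam_gg`` marks
    the two bases encoding the GG of the NGG PAM (as CC on the sense
    strand for a non-template guide).
    """

    footprint: tuple[int, int]  # protospacer + PAM
    protospacer: tuple[int, int]
    seed: tuple[int, int]
    core7: tuple[int, int]
    pam: tuple[int, int]
    pam_gg: tuple[int, int]


def guide_region(candidate: GuideCandidate, params: DesignParams = DesignParams()) -> GuideRegion:
    """Locate protospacer/seed/core/PAM in CDS sense coordinates.

    For the default non-template orientation the PAM appears on the
    sense strand as CCN at offset ``dist5`` with the (reversed)
    protospacer after it; the PAM-proximal seed is therefore the
    sense interval immediately following the CCN.
    """
    i = candidate.dist5
    L = params.spacer_len
    if not candidate.targets_template:
        return GuideRegion(
            footprint=(i, i + L + 3),
            protospacer=(i + 3, i + 3 + L),
            seed=(i + 3, i + 3 + params.seed_len),
            core7=(i + 3, i + 3 + params.exact_core_len),
            pam=(i, i + 3),
            pam_gg=(i, i + 2),
        )
    return GuideRegion(
        footprint=(i, i + L + 3),
        protospacer=(i, i + L),
        seed=(i + L - params.seed_len, i + L),
        core7=(i + L - params.exact_core_len, i + L),
        pam=(i + L, i + L + 3),
        pam_gg=(i + L + 1, i + L + 3),
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass(frozen=True)
class CodonOverlap:
    codon_index: int
    overlap_nt: int
    in_seed: bool
    in_core7: bool
    in_pam: bool
    immutable: bool  # start or stop codon


def map_guide_to_codons(
    feature: Feature,
    candidate: GuideCandidate,
    params: DesignParams = DesignParams(),
) -> list[CodonOverlap]:
    """List every codon overlapping the guide's protospacer+PAM footprint.

    Codon indices are 0-based from the start codon. The start codon and
    the stop codon are flagged immutable.
    """
    if feature.ftype != "CDS":
        raise EscapeDesignError(f"feature {feature.id!r} is not a CDS")
    if feature.non_triplet:
        raise EscapeDesignError(f"CDS {feature.id!r} length not divisible by 3")
    if candidate.feature_id != feature.id:
        raise EscapeDesignError("candidate does not target this feature")
    n_codons = len(feature) // 3
    region = guide_region(candidate, params)
    lo, hi = region.footprint
    if not (0 <= lo and hi <= len(feature)):
        raise EscapeDesignError("candidate footprint outside feature")
    out = []
    for ci in range(lo // 3, (hi + 2) // 3):
        codon_iv = (3 * ci, 3 * ci + 3)
        ov = _overlap(codon_iv, region.footprint)
        if ov == 0:
            continue
        out.append(
            CodonOverlap(
                codon_index=ci,
                overlap_nt=ov,
                in_seed=_overlap(codon_iv, region.seed) > 0,
                in_core7=_overlap(codon_iv, region.core7) > 0,
                in_pam=_overlap(codon_iv, region.pam) > 0,
                immutable=(ci == 0 or ci == n_codons - 1),
            )
        )
    return out


@dataclass
class EscapeAllele:
    """A synonymous recoding of the target that breaks guide pairing."""

    feature_id: str
    spacer: str
    changed_codons: list[tuple[int, str, str]]  # (codon_index, old, new)
    nt_changes_in_seed: int
    nt_changes_in_core7: int
    pam_disrupted: bool
    mutant_cds: str
    predicted_strength: str  # "full" | "partial"

    @property
    def total_nt_changes(self) -> int:
        return sum(
            sum(1 for a, b in zip(old, new) if a != b)
            for _ci, old, new in self.changed_codons
        )

    def variants(self) -> list[tuple[int, str, str]]:
        """Nucleotide changes as (1-based CDS position, ref, alt)."""
        out = []
        for ci, old, new in self.changed_codons:
            for k, (a, b) in enumerate(zip(old, new)):
                if a != b:
                    out.append((3 * ci + k + 1, a, b))
        return out


def _nt_diff_in(iv: tuple[int, int], a: str, b: str) -> int:
    return sum(1 for p in range(iv[0], iv[1]) if a[p] != b[p])


def _pam_intact(mutant_cds: str, candidate: GuideCandidate, params: DesignParams) -> bool:
    region = guide_region(candidate, params)
    lo, hi = region.pam
    pam_sense = mutant_cds[lo:hi]
    pam = pam_sense if candidate.targets_template else revcomp(pam_sense)
    return pam[1:] == params.pam[1:]  # N position is free


def design_escape_alleles(
    feature: Feature,
    candidate: GuideCandidate,
    cds_seq: str,
    min_codon_changes: int = 2,
    params: DesignParams = DesignParams(),
    table: int = 11,
) -> list[EscapeAllele]:
    """Enumerate synonymous escape alleles for a guide.

    Considers every combination of single-codon synonymous substitutions
    at codons overlapping the seed (plus PAM-overlapping codons, which
    can destroy the PAM's GG synonymously). An allele is kept when it
    changes at least ``min_codon_changes`` codons, or when it disrupts
    the PAM regardless of codon count. Every allele is verified
    protein-identical by translation. Results are ordered strongest
    first: most nt changes in the 7-nt core, then most changed codons,
    then fewest total nt changes.

    ``predicted_strength`` is a coarse label: "full" when at least two
    seed codons changed, the PAM is disrupted, or at least one nt change
    falls in the 7-nt core; otherwise "partial".
    """
    if min_codon_changes < 1:
        raise EscapeDesignError("min_codon_changes must be >= 1")
    if len(cds_seq) != len(feature):
        raise EscapeDesignError("cds_seq length does not match feature")
    protein = translate(cds_seq, table)
    region = guide_region(candidate, params)
    overlaps = map_guide_to_codons(feature, candidate, params)
    editable = [
        o for o in overlaps if not o.immutable and (o.in_seed or o.in_pam)
    ]
    if not editable:
        return []
    options: list[list[tuple[int, str, str]]] = []
    for o in editable:
        old = cds_seq[3 * o.codon_index : 3 * o.codon_index + 3]
        syns = synonymous_codons(old, table)
        if syns:
            options.append([(o.codon_index, old, new) for new in sorted(syns)])
    if not options:
        return []
    alleles: list[EscapeAllele] = []
    for k in range(1, len(options) + 1):
        for combo_slots in combinations(options, k):
            for combo in product(*combo_slots):
                mutant = list(cds_seq)
                for ci, _old, new in combo:
                    mutant[3 * ci : 3 * ci + 3] = new
                mutant_cds = "".join(mutant)
                pam_disrupted = not _pam_intact(mutant_cds, candidate, params)
                if len(combo) < min_codon_changes and not pam_disrupted:
                    continue
                n_seed = _nt_diff_in(region.seed, cds_seq, mutant_cds)
                if n_seed == 0 and not pam_disrupted:
                    continue
                n_core = _nt_diff_in(region.core7, cds_seq, mutant_cds)
                if translate(mutant_cds, table) != protein:  # pragma: no cover
                    continue
                seed_codons_changed = sum(
                    1
                    for ci, _o, _n in combo
                    if _overlap((3 * ci, 3 * ci + 3), region.seed) > 0
                    and _nt_diff_in(
                        (max(3 * ci, region.seed[0]), min(3 * ci + 3, region.seed[1])),
                        cds_seq,
                        mutant_cds,
                    )
                    > 0
                )
                strength = (
                    "full"
                    if seed_codons_changed >= 2 or pam_disrupted or n_core >= 1
                    else "partial"
                )
                alleles.append(
                    EscapeAllele(
                        feature_id=feature.id,
                        spacer=candidate.spacer,
                        changed_codons=sorted(combo),
                        nt_changes_in_seed=n_seed,
                        nt_changes_in_core7=n_core,
                        pam_disrupted=pam_disrupted,
                        mutant_cds=mutant_cds,
                        predicted_strength=strength,
                    )
                )
    alleles.sort(
        key=lambda a: (
            -a.nt_changes_in_core7,
            -len(a.changed_codons),
            a.total_nt_changes,
            a.mutant_cds,
        )
    )
    return alleles


@dataclass(frozen=True)
class EscapeReport:
    escaped: bool
    pairing: PairingReport
    pam_intact: bool
    nt_changes_in_seed: int
    nt_changes_in_core7: int
    nt_changes_total: int
    protein_identical: bool


def verify_escape(
    candidate: GuideCandidate,
    original_cds: str,
    mutant_cds: str,
    params: DesignParams = DesignParams(),
    table: int = 11,
) -> EscapeReport:
    """Check whether a recoded CDS escapes its guide.

    Re-extracts the protospacer instance from the mutant CDS and re-runs
    the pairing rule plus the PAM check: escape succeeds iff pairing
    fails or the PAM's GG is destroyed. Indels are not supported.
    """
    if len(mutant_cds) != len(original_cds):
        raise EscapeDesignError("mutant CDS length differs (indels unsupported)")
    region = guide_region(candidate, params)
    lo, hi = region.protospacer
    site_sense = mutant_cds[lo:hi]
    site = site_sense if candidate.targets_template else revcomp(site_sense)
    pairing = validate_pairing(candidate.spacer, site, params)
    pam_intact = _pam_intact(mutant_cds, candidate, params)
    try:
        prot_equal = translate(mutant_cds, table) == translate(original_cds, table)
    except GenomeIOError:
        prot_equal = False
    return EscapeReport(
        escaped=(not pairing.passed) or (not pam_intact),
        pairing=pairing,
        pam_intact=pam_intact,
        nt_changes_in_seed=_nt_diff_in(region.seed, original_cds, mutant_cds),
        nt_changes_in_core7=_nt_diff_in(region.core7, original_cds, mutant_cds),
        nt_changes_total=sum(
            1 for a, b in zip(original_cds, mutant_cds) if a != b
        ),
        protein_identical=prot_equal,
    )
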