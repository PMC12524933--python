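"""Deterministic synthetic genome/annotation fixtures with exact truth.

Every operation in the toolkit is testable without any external genome:
this module generates a random background genome, writes CDS and sRNA
features into it, plants PAM sites (``CC`` dinucleotides with a clean
20-nt downstream window) at requested sense offsets, plants extra copies
of a candidate's seed+PAM specificity instance as off-target decoys, and
*cleans* everything else — any unintended PAM site inside a feature and
any accidental genome-wide match of a tracked specificity pattern is
mutated away (bounded repair loop), so the emitted truth table is exact,
not probabilistic.

The truth table records, per feature, the exact expected candidates
(offset, spacer, PAM), the expected genome-wide binding-site count for
every planted candidate, and the expected sRNA targetability census.
Output is byte-identical for a fixed seed (single ``numpy`` generator,
no global state).

Not modeled: realistic codon bias or oligonucleotide composition — the
background is i.i.d. with a target GC fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from crispritools.genome_io import (
    Feature,
    GenomeRecord,
    revcomp,
    write_fasta,
    write_gff3,
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))

DEFAULT_RETRY_CAP = 1000


class FixtureError(ValueError):
    """Infeasible fixture specification or exhausted repair budget."""


@dataclass(frozen=True)
class GeneSpec:
    """One CDS to synthesize: length must be a multiple of 3 and >= 45."""

    length: int
    strand: str = "+"
    operon_id: str | None = None
    operon_index: int = 0
    planted_pams: tuple[int, ...] = ()  # sense offsets of CCN sites

    def validate(self) -> None:
        if self.length % 3 != 0 or self.length < 45:
            raise FixtureError(f"gene length {self.length} must be a multiple of 3, >= 45")
        for off in self.planted_pams:
            if not (3 <= off and off + 23 <= self.length - 3):
                raise FixtureError(
                    f"planted PAM offset {off} collides with start/stop codon "
                    f"or exceeds gene length {self.length}"
                )


@dataclass(frozen=True)
class SrnaSpec:
    """One sRNA feature; targetable ones get exactly one planted PAM site."""

    length: int
    strand: str = "+"
    targetable: bool = True

    def validate(self) -> None:
        if self.length < 1:
            raise FixtureError("sRNA length must be positive")
        if self.targetable and self.length < 23:
            raise FixtureError(
                f"targetable sRNA needs >= 23 nt (protospacer+PAM), got {self.length}"
            )


@dataclass(frozen=True)
class OfftargetSpec:
    """Plant extra genome copies of one planted candidate's seed+PAM.

    ``gene_index``/``pam_slot`` select the source candidate (slot into
    that gene's ``planted_pams``); each copy alternates +/- strand and
    lands in the reserved background tail of ``record_index``.
    """

    gene_index: int
    pam_slot: int
    copies: int
    record_index: int = 0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_records: int = 1
    record_length: int = 3000
    gc: float = 0.38
    circular: bool = False
    genes: tuple[GeneSpec, ...] = ()
    srnas: tuple[SrnaSpec, ...] = ()
    planted_offtargets: tuple[OfftargetSpec, ...] = ()
    spacer_len: int = 20
    seed_len: int = 12
    retry_cap: int = DEFAULT_RETRY_CAP

    def validate(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise FixtureError("gc must be strictly between 0 and 1")
        if self.n_records < 1 or self.record_length < 200:
            raise FixtureError("need >= 1 record of >= 200 nt")
        for g in self.genes:
            g.validate()
        for s in self.srnas:
            s.validate()
        for ot in self.planted_offtargets:
            if not (0 <= ot.gene_index < len(self.genes)):
                raise FixtureError(f"offtarget gene_index {ot.gene_index} out of range")
            if not (0 <= ot.pam_slot < len(self.genes[ot.gene_index].planted_pams)):
                raise FixtureError(f"offtarget pam_slot {ot.pam_slot} out of range")
            if not (0 <= ot.record_index < self.n_records):
                raise FixtureError("offtarget record_index out of range")


# ---------------------------------------------------------------------------
# internal helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = "".join(_random_seq(rng, 3, gc))
        if codon not in _STOPS:
            return codon


class _Builder:
    """Mutable genome under construction, with protected positions."""

    def __init__(self, spec: FixtureSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.seqs: list[list[str]] = [
            _random_seq(rng, spec.record_length, spec.gc)
            for _ in range(spec.n_records)
        ]
        self.protected: set[tuple[int, int]] = set()  # (record_idx, pos)
        self.features: list[Feature] = []
        self.feature_strand: dict[str, str] = {}

    # sense-coordinate access -------------------------------------------------
    def sense(self, feat: Feature) -> str:
        seq = self.seqs[self._rec_idx(feat.record_id)]
        plus = "".join(seq[feat.start : feat.end])
        return plus if feat.strand == "+" else revcomp(plus)

    def set_sense(self, feat: Feature, offset: int, base: str) -> None:
        ri = self._rec_idx(feat.record_id)
        if feat.strand == "+":
            pos = feat.start + offset
            self.seqs[ri][pos] = base
        else:
            pos = feat.end - 1 - offset
            self.seqs[ri][pos] = revcomp(base)

    def genomic_pos(self, feat: Feature, offset: int) -> int:
        return feat.start + offset if feat.strand == "+" else feat.end - 1 - offset

    def _rec_idx(self, record_id: str) -> int:
        return int(record_id.rsplit("_", 1)[1])

    def protect_sense_range(self, feat: Feature, lo: int, hi: int) -> None:
        ri = self._rec_idx(feat.record_id)
        for off in range(lo, hi):
            self.protected.add((ri, self.genomic_pos(feat, off)))

    # mutation with CDS stop-codon safety -------------------------------------
    def _codon_safe(self, feat: Feature, offset: int, base: str) -> bool:
        if feat.ftype != "CDS":
            return True
        ci = offset // 3
        sense = self.sense(feat)
        codon = list(sense[3 * ci : 3 * ci + 3])
        codon[offset % 3] = base
        return "".join(codon) not in _STOPS

    def mutate_sense(self, feat: Feature, offset: int, avoid: set[str]) -> bool:
        """Replace the sense base at ``offset`` avoiding given bases; False if stuck."""
        ri = self._rec_idx(feat.record_id)
        if (ri, self.genomic_pos(feat, offset)) in self.protected:
            return False
        current = self.sense(feat)[offset]
        choices = [b for b in "AGT" if b not in avoid and b != current]
        order = list(self.rng.permutation(choices)) if choices else []
        for base in order:
            if self._codon_safe(feat, offset, base):
                self.set_sense(feat, offset, base)
                return True
        return False


def _clean_feature(builder: _Builder, feat: Feature, keep: set[int], site_len: int) -> bool:
    """Remove every unintended CCN+window site; True when any change made."""
    changed = False
    for _ in range(builder.spec.retry_cap):
        sense = builder.sense(feat)
        offending = [
            i
            for i in range(len(sense) - site_len + 1)
            if sense[i : i + 2] == "CC" and i not in keep
        ]
        if not offending:
            return changed
        i = offending[0]
        if not (builder.mutate_sense(feat, i + 1, avoid={"C"})
                or builder.mutate_sense(feat, i, avoid={"C"})):
            raise FixtureError(
                f"cannot clean CC at offset {i} of {feat.id} (protected/codon-locked)"
            )
        changed = True
    raise FixtureError(f"retry cap exceeded cleaning feature {feat.id}")


def _plant_pam(builder: _Builder, feat: Feature, offset: int) -> None:
    """Write CC at sense offset; keep flanking bases from forming extra CCs."""
    for k, base in ((0, "C"), (1, "C")):
        if not builder._codon_safe(feat, offset + k, base):  # pragma: no cover
            raise FixtureError(f"cannot plant CC at {feat.id}:{offset} (stop codon)")
        builder.set_sense(feat, offset + k, base)
    builder.protect_sense_range(feat, offset, offset + 2)
    sense = builder.sense(feat)
    # flanking C would shift the site: clear it before protecting the window
    if offset >= 1 and sense[offset - 1] == "C":
        if not builder.mutate_sense(feat, offset - 1, avoid={"C"}):
            raise FixtureError(f"cannot clear flanking C at {feat.id}:{offset - 1}")
    if sense[offset + 2] == "C":
        if not builder.mutate_sense(feat, offset + 2, avoid={"C"}):
            raise FixtureError(f"cannot clear PAM-N C at {feat.id}:{offset + 2}")


def _pattern_positions(seq: str, pattern: str) -> list[int]:
    """Start positions where pattern (N = any base) matches seq exactly."""
    plen = len(pattern)
    out = []
    for i in range(len(seq) - plen + 1):
        if all(p == "N" or p == seq[i + k] for k, p in enumerate(pattern)):
            out.append(i)
    return out


def _count_pattern(builder: _Builder, pattern: str) -> list[tuple[int, int, str]]:
    hits = []
    rc = revcomp(pattern)
    for ri, seq_list in enumerate(builder.seqs):
        seq = "".join(seq_list)
        for pos in _pattern_positions(seq, pattern):
            hits.append((ri, pos, "+"))
        for pos in _pattern_positions(seq, rc):
            hits.append((ri, pos, "-"))
    return hits


def generate_fixture(spec: FixtureSpec) -> tuple[list[GenomeRecord], list[Feature], dict]:
    """Build genome records, features and the exact truth table.

    Deterministic for a given ``spec.seed``. Raises :class:`FixtureError`
    when the features do not fit the records or the repair budget is
    exhausted (e.g. compositions that cannot be cleaned).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec, rng)
    site_len = spec.spacer_len + 3

    # ---- lay out features on record 0
    cursor = 60
    for gi, gene in enumerate(spec.genes):
        feat = Feature(
            id=f"gene_{gi:02d}",
            record_id="rec_0",
            start=cursor,
            end=cursor + gene.length,
            strand=gene.strand,
            ftype="CDS",
            operon_id=gene.operon_id,
            operon_index=gene.operon_index,
        )
        builder.features.append(feat)
        cursor = feat.end + 47
    for si, srna in enumerate(spec.srnas):
        feat = Feature(
            id=f"srna_{si:02d}",
            record_id="rec_0",
            start=cursor,
            end=cursor + srna.length,
            strand=srna.strand,
            ftype="sRNA",
        )
        builder.features.append(feat)
        cursor = feat.end + 47
    tail_needed = 25 * sum(ot.copies for ot in spec.planted_offtargets if ot.record_index == 0)
    if cursor + tail_needed + 40 > spec.record_length:
        raise FixtureError(
            f"features need {cursor + tail_needed + 40} nt but record_length is "
            f"{spec.record_length}"
        )

    genes_by_feat = {f"gene_{gi:02d}": g for gi, g in enumerate(spec.genes)}
    srnas_by_feat = {f"srna_{si:02d}": s for si, s in enumerate(spec.srnas)}

    # ---- write CDS sequences (start codon, sense codons, stop codon)
    for feat in builder.features:
        if feat.ftype != "CDS":
            continue
        n_codons = len(feat) // 3
        codons = ["ATG"] + [
            _random_sense_codon(rng, spec.gc) for _ in range(n_codons - 2)
        ] + ["TAA"]
        sense = "".join(codons)
        for off, base in enumerate(sense):
            builder.set_sense(feat, off, base)
        builder.protect_sense_range(feat, 0, 3)
        builder.protect_sense_range(feat, len(feat) - 3, len(feat))

    # ---- plant PAM sites; choose sRNA offsets
    planted: dict[str, list[int]] = {}
    for feat in builder.features:
        if feat.ftype == "CDS":
            offsets = sorted(genes_by_feat[feat.id].planted_pams)
        else:
            s = srnas_by_feat[feat.id]
            offsets = (
                [int(rng.integers(0, len(feat) - site_len + 1))] if s.targetable else []
            )
        planted[feat.id] = offsets
        for off in offsets:
            _plant_pam(builder, feat, off)

    # ---- clean features, then freeze planted footprints
    for feat in builder.features:
        _clean_feature(builder, feat, set(planted[feat.id]), site_len)
        # protect the full footprint so later repairs never alter spacers
        for off in planted[feat.id]:
            builder.protect_sense_range(feat, off, off + site_len)

    candidates: dict[tuple[str, int], dict] = {}
    for feat in builder.features:
        sense = builder.sense(feat)
        for slot, off in enumerate(planted[feat.id]):
            spacer = revcomp(sense[off + 3 : off + 3 + spec.spacer_len])
            pam = revcomp(sense[off : off + 3])
            seed_part = spacer[-spec.seed_len :]
            candidates[(feat.id, slot)] = {
                "feature_id": feat.id,
                "dist5": off,
                "spacer": spacer,
                "pam": pam,
                "pattern": seed_part + "NGG",
                "expected_sites": 1,
            }

    # ---- plant off-target copies in the background tail
    tail_pos = cursor + 20
    for ot in spec.planted_offtargets:
        source = candidates[(f"gene_{ot.gene_index:02d}", ot.pam_slot)]
        instance = source["spacer"][-spec.seed_len :] + "AGG"
        for c in range(ot.copies):
            text = instance if c % 2 == 0 else revcomp(instance)
            if tail_pos + len(text) + 2 > spec.record_length:
                raise FixtureError("record tail too small for off-target copies")
            for k, base in enumerate(text):
                builder.seqs[ot.record_index][tail_pos + k] = base
                builder.protected.add((ot.record_index, tail_pos + k))
            # keep copy boundaries from bleeding into each other
            tail_pos += len(text) + 7
        source["expected_sites"] += ot.copies

    # ---- repair loop: kill accidental pattern matches and re-clean
    expected_hits: dict[tuple[str, int], int] = {
        key: c["expected_sites"] for key, c in candidates.items()
    }
    for _round in range(spec.retry_cap):
        dirty = False
        for feat in builder.features:
            if _clean_feature(builder, feat, set(planted[feat.id]), site_len):
                dirty = True
        for key, cand in candidates.items():
            hits = _count_pattern(builder, cand["pattern"])
            excess = len(hits) - expected_hits[key]
            if excess <= 0:
                continue
            dirty = True
            repaired = False
            for ri, pos, _strand in hits:
                for k in range(len(cand["pattern"])):
                    if (ri, pos + k) in builder.protected:
                        continue
                    cur = builder.seqs[ri][pos + k]
                    feat_here = next(
                        (
                            f for f in builder.features
                            if builder._rec_idx(f.record_id) == ri
                            and f.start <= pos + k < f.end
                        ),
                        None,
                    )
                    if feat_here is not None:
                        off = (
                            pos + k - feat_here.start
                            if feat_here.strand == "+"
                            else feat_here.end - 1 - (pos + k)
                        )
                        if builder.mutate_sense(feat_here, off, avoid=set()):
                            repaired = True
                    else:
                        alts = [b for b in "ACGT" if b != cur]
                        builder.seqs[ri][pos + k] = str(
                            alts[int(builder.rng.integers(0, len(alts)))]
                        )
                        repaired = True
                    if repaired:
                        break
                if repaired:
                    break
            if not repaired:
                raise FixtureError(
                    f"cannot repair accidental match of {cand['pattern']}"
                )
        if not dirty:
            break
    else:
        raise FixtureError("retry cap exceeded in fixture repair loop")

    # ---- finalize
    records = [
        GenomeRecord(
            id=f"rec_{ri}",
            seq="".join(builder.seqs[ri]),
            circular=spec.circular,
        )
        for ri in range(spec.n_records)
    ]
    truth_features = {}
    for feat in builder.features:
        expected = [
            {
                "dist5": candidates[(feat.id, slot)]["dist5"],
                "spacer": candidates[(feat.id, slot)]["spacer"],
                "pam": candidates[(feat.id, slot)]["pam"],
            }
            for slot in range(len(planted[feat.id]))
        ]
        truth_features[feat.id] = {
            "ftype": feat.ftype,
            "strand": feat.strand,
            "length": len(feat),
            "expected_candidates": expected,
            "targetable": len(expected) > 0,
        }
    truth = {
        "seed": spec.seed,
        "records": [
            {"id": r.id, "length": len(r), "circular": r.circular} for r in records
        ],
        "features": truth_features,
        "offtarget_counts": {
            f"{fid}:{slot}": c["expected_sites"]
            for (fid, slot), c in candidates.items()
        },
        "srna_census": {
            "n_targetable": sum(1 for s in spec.srnas if s.targetable),
            "n_total": len(spec.srnas),
        },
    }
    return records, builder.features, truth


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Generate and write genome.fasta, features.gff3, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, features, truth = generate_fixture(spec)
    fasta = outdir / "genome.fasta"
    gff = outdir / "features.gff3"
    truth_path = outdir / "truth.json"
    write_fasta(records, fasta)
    write_gff3(features, gff)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return fasta, gff, truth_path
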