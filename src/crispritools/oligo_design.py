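"""Quick-fusion guide-swap cloning oligos and sgRNA cassette assembly.

Swapping the 20-nt guide in a linearized sgRNA expression vector uses a
pair of complementary 50-nt primers: 15 nt overlapping the 5' end of the
linearized vector, the 20-nt guide, then 15 nt overlapping the 3' end.
The annealed duplex is fused directly into the vector (anneal in TEN
buffer — 10 mM Tris, 1 mM EDTA, 100 mM NaCl, pH 8 — 95 °C 5 min, slow
cool; recorded as metadata, not modeled). The vector overlap sequences
are user configuration; no vector database is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from crispritools.genome_io import revcomp

ANNEALING_PROTOCOL = (
    "anneal equimolar oligos in TEN buffer (10 mM Tris, 1 mM EDTA, "
    "100 mM NaCl, pH 8); 95 C for 5 min, slow-cool to room temperature"
)

_UNAMBIG = set("ACGT")


class OligoDesignError(ValueError):
    pass


@dataclass(frozen=True)
class OligoPair:
    """Two complementary 50-nt guide-swap primers (both written 5'->3')."""

    fwd: str
    rev: str
    spacer: str
    up15: str
    down15: str


def _check(seq: str, name: str, length: int) -> None:
    if len(seq) != length:
        raise OligoDesignError(f"{name} must be {length} nt, got {len(seq)}")
    bad = set(seq) - _UNAMBIG
    if bad:
        raise OligoDesignError(f"{name}: ambiguous bases {sorted(bad)}")


def make_guide_swap_oligos(spacer: str, up15: str, down15: str) -> OligoPair:
    """Build the complementary 50-nt primer pair 15 + 20 + 15.

    ``fwd = up15 + spacer + down15``; ``rev`` is its reverse complement.
    Pure and deterministic.
    """
    _check(spacer, "spacer", 20)
    _check(up15, "up15", 15)
    _check(down15, "down15", 15)
    fwd = up15 + spacer + down15
    return OligoPair(fwd=fwd, rev=revcomp(fwd), spacer=spacer, up15=up15, down15=down15)


def assemble_sgrna_cassette(spacer: str, scaffold_seq: str) -> tuple[str, dict]:
    """Concatenate spacer + sgRNA scaffold into the transcribed cassette.

    The scaffold (crRNA-tracrRNA chimera downstream of the spacer) must
    be supplied by the user — no default is shipped. Returns the cassette
    and a provenance metadata dict.
    """
    if not scaffold_seq:
        raise OligoDesignError("sgRNA scaffold sequence is required (none bundled)")
    if len(spacer) != 20:
        raise OligoDesignError(f"spacer must be 20 nt, got {len(spacer)}")
    meta = {
        "spacer_len": len(spacer),
        "scaffold_len": len(scaffold_seq),
        "cassette_len": len(spacer) + len(scaffold_seq),
        "scaffold_source": "user-supplied",
    }
    return spacer + scaffold_seq, meta


def write_oligo_sheet(
    pairs: Iterable[tuple[str, OligoPair]], path, fmt: str = "tsv"
) -> None:
    """Write an order sheet: TSV (name, sequence, length) or FASTA."""
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write(f"# guide-swap oligos; {ANNEALING_PROTOCOL}\n")
            fh.write("name\tsequence\tlength\n")
            for name, pair in pairs:
                fh.write(f"{name}_FW\t{pair.fwd}\t{len(pair.fwd)}\n")
                fh.write(f"{name}_RV\t{pair.rev}\t{len(pair.rev)}\n")
        elif fmt == "fasta":
            for name, pair in pairs:
                fh.write(f">{name}_FW\n{pair.fwd}\n>{name}_RV\n{pair.rev}\n")
        else:
            raise OligoDesignError(f"unknown oligo sheet format {fmt!r}")
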