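"""Independent brute-force oracles for cross-checking the toolkit.

Everything here is written the dumbest correct way — position-by-position
sliding windows, literal codon dictionary — and shares no code with the
production scanning/translation paths it verifies.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# Standard genetic code (identical codon->aa mapping for NCBI table 11).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def brute_force_candidates(feature, record, spacer_len: int = 20):
    """All non-template-strand candidates as a set of tuples.

    Walks every 23-nt genomic window on both strands, requires an NGG
    PAM 3' of the protospacer on the window's strand, the whole
    footprint inside the feature, the protospacer strand opposite the
    feature strand (sgRNA pairs with the sense strand), and no N.
    Returns {(spacer, dist5, proto_start, proto_end, pam_strand)}.
    """
    seq = record.seq
    flen = spacer_len + 3
    found = set()
    for s in range(len(seq) - flen + 1):
        window = seq[s : s + flen]
        if "N" in window:
            continue
        # protospacer on '+': proto then PAM, left to right
        if window[spacer_len + 1 : spacer_len + 3] == "GG" and feature.strand == "-":
            if feature.start <= s and s + flen <= feature.end:
                dist5 = feature.end - s - flen
                found.add((window[:spacer_len], dist5, s, s + spacer_len, "+"))
        # protospacer on '-': PAM then proto in '+' coordinates
        if window[0:2] == "CC" and feature.strand == "+":
            if feature.start <= s and s + flen <= feature.end:
                dist5 = s - feature.start
                found.add(
                    (rc(window[3:]), dist5, s + 3, s + flen, "-")
                )
    return found


def brute_force_site_count(pattern: str, records) -> int:
    """Occurrences of pattern (N in pattern = any of ACGT) on both strands.

    Wraps the origin only for circular records; genomic N matches nothing.
    """

    def matches(seq: str, i: int, pat: str) -> bool:
        for k, p in enumerate(pat):
            c = seq[(i + k) % len(seq)]
            if c == "N":
                return False
            if p != "N" and p != c:
                return False
        return True

    total = 0
    for record in records:
        seq = record.seq
        limit = len(seq) if record.circular else len(seq) - len(pattern) + 1
        for pat in (pattern, rc(pattern)):
            for i in range(max(limit, 0)):
                if matches(seq, i, pat):
                    total += 1
    return total


def pairing_run_oracle(spacer: str, site: str) -> int:
    """Contiguous matched run from the PAM-proximal (3') end."""
    run = 0
    for a, b in zip(reversed(spacer), reversed(site)):
        if a != b:
            break
        run += 1
    return run
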