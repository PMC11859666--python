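"""miRNA canonical seed-site detection, shared-sponge identification and
ORF finding.

Seed-site definitions (exact Watson-Crick complementarity, no wobble):

* 6mer      — transcript match to the reverse complement of miRNA
              positions 2-7 (the seed);
* 7mer-m8   — seed match extended by complementarity to miRNA position 8
              (one nt 5' of the site on the transcript);
* 7mer-A1   — seed match plus an adenosine in the transcript opposite
              miRNA position 1 (the 3' end of the site);
* 8mer      — both extensions.

Types are mutually exclusive per locus with priority
8mer > 7mer-m8 > 7mer-A1 > 6mer.  Thermodynamic scoring, conservation and
3'-compensatory pairing are deliberately out of scope: the explicit string
rule is what keeps results reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    id: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.id}: miRNA alphabet must be ACGU")
        if len(seq) < 18:
            raise ValueError(f"{self.id}: miRNA shorter than 18 nt")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    transcript_id: str
    mirna_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    start: int      # 0-based on the transcript
    site_sequence: str


@dataclass
class SharedSponge:
    mirna_id: str
    pseudogene_sites: list
    parent_sites: list

    def __post_init__(self):
        if not self.pseudogene_sites or not self.parent_sites:
            raise ValueError("shared sponge requires sites in both transcripts")


@dataclass(frozen=True)
class ORF:
    start: int  # 0-based on the transcript
    end: int    # exclusive, includes the stop codon
    frame: int  # 0 | 1 | 2
    aa_length: int  # codons from ATG inclusive to stop exclusive

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


# ---------------------------------------------------------------------------
# seed sites

def find_seed_sites(transcript_seq: str, mirna: MiRNA,
                    transcript_id: str = "") -> list:
    """All canonical seed sites of one miRNA in a transcript.

    The transcript is scanned for the 6mer core (reverse complement of
    miRNA positions 2-7); each core locus is then typed by checking the m8
    extension (transcript base 5' of the core pairing miRNA position 8) and
    the A1 anchor (an A immediately 3' of the core).  One site per core
    locus, at the highest matching type.
    """
    if len(mirna.sequence) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    tx = _to_dna(transcript_seq)
    mir = _to_dna(mirna.sequence)
    core = _revcomp(mir[1:7])       # seed = positions 2-7 (1-based)
    m8_base = _revcomp(mir[7])      # pairs transcript base 5' of the core
    sites = []
    pos = tx.find(core)
    while pos != -1:
        has_m8 = pos > 0 and tx[pos - 1] == m8_base
        has_a1 = pos + 6 < len(tx) and tx[pos + 6] == "A"
        if has_m8 and has_a1:
            stype, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            stype, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            stype, start, end = "7mer-A1", pos, pos + 7
        else:
            stype, start, end = "6mer", pos, pos + 6
        sites.append(
            SeedSite(transcript_id, mirna.id, stype, start, tx[start:end])
        )
        pos = tx.find(core, pos + 1)
    return sites


def shared_mirnas(pseudogene_seq: str, parent_utr_seq: str,
                  mirna_set: Iterable) -> dict:
    """miRNAs with at least one seed site in both sequences, plus Venn
    counts (pseudogene-only / shared / parent-only)."""
    if not pseudogene_seq or not parent_utr_seq:
        raise ValueError("both sequences must be non-empty")
    shared, pg_only, parent_only = [], 0, 0
    for mirna in mirna_set:
        pg_sites = find_seed_sites(pseudogene_seq, mirna, "pseudogene")
        pa_sites = find_seed_sites(parent_utr_seq, mirna, "parent")
        if pg_sites and pa_sites:
            shared.append(SharedSponge(mirna.id, pg_sites, pa_sites))
        elif pg_sites:
            pg_only += 1
        elif pa_sites:
            parent_only += 1
    return {
        "shared": shared,
        "venn": {"pseudogene_only": pg_only, "shared": len(shared),
                 "parent_only": parent_only},
    }


# ---------------------------------------------------------------------------
# ORF finding

STOP_CODONS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: str) -> list:
    """All ATG -> stop ORFs in the three forward frames.

    aa_length counts codons from the ATG (inclusive) to the stop
    (exclusive); ORFs without an in-frame stop are not reported.
    """
    s = _to_dna(seq)
    orfs = []
    for frame in range(3):
        i = frame
        while i + 3 <= len(s):
            if s[i:i + 3] == "ATG":
                j = i + 3
                while j + 3 <= len(s):
                    if s[j:j + 3] in STOP_CODONS:
                        orfs.append(ORF(i, j + 3, frame, (j - i) // 3))
                        break
                    j += 3
            i += 3
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def longest_orf(seq: str):
    """The longest ORF by amino-acid length (ties: leftmost); None if the
    sequence contains no complete ORF."""
    orfs = find_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.aa_length, -o.start))
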