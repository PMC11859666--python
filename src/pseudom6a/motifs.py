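"""Discriminative ungapped motif discovery in peak sequences versus
shuffled controls.

The search enumerates every exact word of width 4-8 present in the target
set, scores each with a one-sided exact test on presence/absence counts
(targets vs per-sequence mononucleotide-shuffled controls), generalizes the
best word position-by-position over the IUPAC alphabet while the p-value
improves, reports the motif, erases its matches from the targets and
repeats — stopping when the best candidate no longer clears a Bonferroni
threshold on the number of words tested.

Alphabet handling: RNA input is normalized to DNA internally (U -> T) and
motifs are rendered back as RNA in reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC.items()}

RRACH = "RRACH"


@dataclass
class MotifResult:
    pattern: str   # IUPAC, rendered as RNA (T -> U)
    width: int
    n_target: int
    n_control: int
    p_value: float
    rank: int

    def __post_init__(self):
        if not 4 <= self.width <= 8:
            raise ValueError("motif width must be in [4, 8]")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _to_rna(pattern: str) -> str:
    return pattern.replace("T", "U")


def shuffle_controls(sequences: Iterable, seed: int) -> list:
    """Per-sequence mononucleotide shuffle (base multiset preserved)."""
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        chars = list(seq)
        rng.shuffle(chars)
        out.append("".join(chars))
    return out


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern)
    )


def _presence(pattern: str, sequences: list) -> int:
    rx = _pattern_regex(pattern)
    return sum(1 for s in sequences if rx.search(s))


def _enrichment_p(n_t: int, T: int, n_c: int, C: int) -> float:
    """One-sided exact p for target presence exceeding control presence:
    hypergeometric tail of the 2x2 table [[n_t, T-n_t], [n_c, C-n_c]]."""
    return float(stats.hypergeom.sf(n_t - 1, T + C, n_t + n_c, T))


def _count_words(sequences: list, width: int) -> dict:
    """word -> number of sequences containing it (presence counting)."""
    counts: dict = {}
    for seq in sequences:
        seen = set()
        for i in range(len(seq) - width + 1):
            w = seq[i:i + width]
            if "N" in w or w in seen:
                continue
            seen.add(w)
            counts[w] = counts.get(w, 0) + 1
    return counts


def _generalize(word: str, targets: list, controls: list,
                p0: float) -> tuple:
    """Greedy IUPAC generalization: accept a degenerate code at a position
    iff it strictly improves the exact-test p-value."""
    T, C = len(targets), len(controls)
    pattern = list(word)
    best_p = p0
    improved = True
    while improved:
        improved = False
        for i in range(len(pattern)):
            current = frozenset(IUPAC[pattern[i]])
            for code, bases in IUPAC.items():
                if not current < frozenset(bases):
                    continue
                trial = pattern.copy()
                trial[i] = code
                tp = "".join(trial)
                p = _enrichment_p(_presence(tp, targets), T,
                                  _presence(tp, controls), C)
                if p < best_p:
                    best_p = p
                    pattern = trial
                    improved = True
    return "".join(pattern), best_p


def _erase(pattern: str, sequences: list) -> list:
    """Replace every match of the pattern with N so it can seed no further
    words (presence counts strictly decrease)."""
    rx = _pattern_regex(pattern)
    out = []
    for seq in sequences:
        prev = None
        while prev != seq:
            prev = seq
            seq = rx.sub(lambda m: "N" * len(m.group(0)), seq, count=1)
        out.append(seq)
    return out


def find_motifs(targets: Iterable, controls: Iterable,
                widths: Iterable = range(4, 9), max_motifs: int = 5,
                alpha: float = 0.05) -> list:
    """Ranked discriminative motifs in ``targets`` versus ``controls``."""
    targets = [_to_dna(s) for s in targets]
    controls = [_to_dna(s) for s in controls]
    if not targets:
        return []
    T, C = len(targets), len(controls)
    widths = list(widths)
    results = []
    work = targets
    for rank in range(1, max_motifs + 1):
        candidates = {}
        for w in widths:
            candidates.update(_count_words(work, w))
        if not candidates:
            break
        control_counts = {}
        for w in widths:
            control_counts.update(_count_words(controls, w))
        words = list(candidates)
        pvals = np.array([
            _enrichment_p(candidates[w], T, control_counts.get(w, 0), C)
            for w in words
        ])
        n_tested = len(words)
        best_i = int(np.argmin(pvals))
        threshold = alpha / n_tested
        if pvals[best_i] >= threshold:
            break
        word = words[best_i]
        pattern, p = _generalize(word, work, controls, float(pvals[best_i]))
        n_t = _presence(pattern, work)
        n_c = _presence(pattern, controls)
        results.append(
            MotifResult(_to_rna(pattern), len(pattern), n_t, n_c, p, rank)
        )
        work = _erase(pattern, work)
    return results


def match_rrach(pattern: str) -> bool:
    """True iff the pattern's match set is contained in RRACH's at some
    alignment offset (R = A/G, H = A/C/U)."""
    pattern = _to_dna(pattern)
    for c in pattern:
        if c not in IUPAC:
            raise ValueError(f"non-IUPAC symbol {c!r}")
    if len(pattern) > len(RRACH):
        return False
    target_sets = [frozenset(IUPAC[c]) for c in RRACH]
    pat_sets = [frozenset(IUPAC[c]) for c in pattern]
    for offset in range(len(RRACH) - len(pattern) + 1):
        if all(ps <= target_sets[offset + i] for i, ps in enumerate(pat_sets)):
            return True
    return False


def motifs_to_frame(results: list):
    import pandas as pd

    return pd.DataFrame(
        [
            {"pattern": r.pattern, "width": r.width, "n_target": r.n_target,
             "n_control": r.n_control, "p_value": r.p_value, "rank": r.rank}
            for r in results
        ]
    )


def write_meme(results: list, path: str, alphabet: str = "ACGU") -> None:
    """Minimal MEME-format motif output (uniform-background PWMs built from
    the IUPAC match sets)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for r in results:
            fh.write(f"MOTIF {r.pattern}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {r.width} "
                f"nsites= {r.n_target} E= {r.p_value:.3g}\n"
            )
            for c in _to_dna(r.pattern):
                allowed = IUPAC[c]
                row = [
                    (1.0 / len(allowed)) if b in allowed else 0.0
                    for b in "ACGT"
                ]
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
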