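"""Full-length, 100 %-identity peptide-to-proteome matching.

A predicted gene counts as translated only if at least one peptide matches
its protein over the peptide's entire length with perfect identity - i.e.
exact substring occurrence.  Matching runs a single Aho-Corasick pass over
the proteome, which is equivalent to (and tested against) the naive scan.
Leucine and isoleucine are deliberately not equated.
"""

from __future__ import annotations

import logging
from collections import deque

import pandas as pd

from .records import PeptideHit

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class _AhoCorasick:
    """Minimal Aho-Corasick automaton reporting all pattern occurrences."""

    def __init__(self, patterns: dict[str, list[str]]):
        # patterns: sequence -> ids sharing that sequence
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.output: list[list[tuple[str, int]]] = [[]]  # (pattern_id, length)
        for seq, ids in patterns.items():
            state = 0
            for ch in seq:
                nxt = self.goto[state].get(ch)
                if nxt is None:
                    nxt = len(self.goto)
                    self.goto[state][ch] = nxt
                    self.goto.append({})
                    self.fail.append(0)
                    self.output.append([])
                state = nxt
            for pid in ids:
                self.output[state].append((pid, len(seq)))
        queue = deque()
        for state in self.goto[0].values():
            queue.append(state)
        while queue:
            s = queue.popleft()
            for ch, t in self.goto[s].items():
                queue.append(t)
                f = self.fail[s]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[t] = self.goto[f].get(ch, 0) if self.goto[f].get(ch, 0) != t else 0
                self.output[t] = self.output[t] + self.output[self.fail[t]]

    def scan(self, text: str):
        state = 0
        for pos, ch in enumerate(text):
            while state and ch not in self.goto[state]:
                state = self.fail[state]
            state = self.goto[state].get(ch, 0)
            for pid, length in self.output[state]:
                yield pid, pos - length + 1


def match_peptides(
    peptides: dict[str, str], proteome: dict[str, str]
) -> tuple[list[PeptideHit], pd.Series]:
    """All exact full-length peptide occurrences plus a per-gene flag.

    Peptides containing characters outside the 20-letter amino-acid alphabet
    are skipped with a warning.  Returns hits sorted by (protein, start,
    peptide id) and a boolean Series over the proteome's gene ids.
    """
    clean: dict[str, list[str]] = {}
    seqs: dict[str, str] = {}
    for pid, seq in peptides.items():
        s = seq.upper()
        if not s or set(s) - _AA_ALPHABET:
            logger.warning("skipping peptide %s with illegal characters", pid)
            continue
        clean.setdefault(s, []).append(pid)
        seqs[pid] = s
    hits: list[PeptideHit] = []
    if clean:
        ac = _AhoCorasick(clean)
        for prot_id in sorted(proteome):
            text = proteome[prot_id].upper()
            for pid, start in ac.scan(text):
                hits.append(PeptideHit(pid, seqs[pid], prot_id, start))
    hits.sort(key=lambda h: (h.protein_id, h.start, h.peptide_id))
    flagged = {h.protein_id for h in hits}
    flag = pd.Series(
        [g in flagged for g in proteome], index=list(proteome), name="peptide"
    )
    return hits, flag


def naive_match(peptides: dict[str, str], proteome: dict[str, str]) -> set[tuple]:
    """Quadratic reference scan (the correctness oracle for the automaton)."""
    out = set()
    for pid, pep in peptides.items():
        p = pep.upper()
        if not p or set(p) - _AA_ALPHABET:
            continue
        for prot_id, prot in proteome.items():
            text = prot.upper()
            start = text.find(p)
            while start != -1:
                out.add((pid, prot_id, start))
                start = text.find(p, start + 1)
    return out
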