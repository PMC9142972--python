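"""RNA secondary-structure folding engines.

The precursor-validation stage only needs one primitive: fold a sequence
into a minimum-free-energy dot-bracket structure.  ``ViennaEngine`` wraps
the ViennaRNA thermodynamic folder and is the production engine.
``PairMaxEngine`` is a self-contained base-pair-maximisation folder (fixed
-1 kcal/mol per pair) kept so structural plumbing can be unit-tested in
isolation; thermodynamic quantities (MFE, MFEI) are only meaningful from
the thermodynamic engine.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Protocol

from .util import to_rna


class FoldingEngine(Protocol):
    """Contract: deterministic ``fold(sequence) -> (dot-bracket, MFE)``."""

    def fold(self, sequence: str) -> tuple[str, float]: ...


@lru_cache(maxsize=200_000)
def _vienna_fold(rna: str) -> tuple[str, float]:
    import RNA

    structure, mfe = RNA.fold(rna)
    return structure, float(mfe)


class ViennaEngine:
    """Minimum-free-energy folding via the ViennaRNA bindings (kcal/mol).

    Results are memoised process-wide: the pipeline folds the same
    precursor windows repeatedly (generation-time verification, known-
    precursor validation, discovery validation of isomiRs of one locus).
    """

    def fold(self, sequence: str) -> tuple[str, float]:
        return _vienna_fold(to_rna(sequence))


class PairMaxEngine:
    """Nussinov-style base-pair maximisation with a -1 kcal/mol-per-pair
    energy proxy.  Minimum hairpin loop of 3 nt; Watson-Crick plus G:U
    pairs.  Deterministic traceback (prefers unpaired, then the smallest
    partner index)."""

    _pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    min_loop = 3

    def fold(self, sequence: str) -> tuple[str, float]:
        s = to_rna(sequence)
        n = len(s)
        if n == 0:
            return "", 0.0
        can = [[(s[i], s[j]) in self._pairs for j in range(n)] for i in range(n)]
        best = [[0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(n - span):
                j = i + span
                v = best[i][j - 1]
                for k in range(i, j - self.min_loop):
                    if can[k][j]:
                        left = best[i][k - 1] if k > i else 0
                        inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        v = max(v, left + inner + 1)
                best[i][j] = v
        structure = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or best[i][j] == 0:
                continue
            if best[i][j] == best[i][j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - self.min_loop):
                if can[k][j]:
                    left = best[i][k - 1] if k > i else 0
                    inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if left + inner + 1 == best[i][j]:
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        break
        n_pairs = structure.count("(")
        return "".join(structure), -1.0 * n_pairs


def pair_table(structure: str) -> list[int]:
    """Partner index (0-based) per position, -1 if unpaired."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            table[i] = j
            table[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return table
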