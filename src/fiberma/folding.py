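"""RNA secondary-structure prediction backends.

The default backend adapts the ViennaRNA thermodynamic folder (deterministic
dot-bracket + MFE).  A built-in base-pair-maximisation folder with simple
per-pair energies exists solely for dependency-free testing and labels
itself as non-thermodynamic in its name.
"""

from __future__ import annotations

from typing import Protocol

from .errors import AlphabetError, InputError
from .seq import to_rna

MAX_FOLD_LEN = 600


class Folder(Protocol):
    name: str

    def fold(self, seq: str) -> tuple[str, float]: ...


def _check_fold_input(seq: str) -> str:
    s = to_rna(seq.upper())
    bad = set(s) - set("ACGU")
    if bad:
        raise AlphabetError(f"cannot fold sequence with characters {sorted(bad)!r}")
    if len(s) > MAX_FOLD_LEN:
        raise InputError(f"sequence length {len(s)} exceeds folding limit {MAX_FOLD_LEN}")
    return s


class ViennaFolder:
    """Thermodynamic folding via the ViennaRNA bindings (kcal/mol MFE)."""

    name = "viennarna"

    def __init__(self):
        import RNA  # deferred: optional at import time

        self._rna = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        s = _check_fold_input(seq)
        structure, mfe = self._rna.fold(s)
        return structure, float(mfe)


class NussinovFolder:
    """Base-pair maximisation with simple pair energies.

    Non-thermodynamic fallback for dependency-free testing only: maximises
    summed pair scores (GC 3, AU 2, GU 1; min hairpin loop 3) and reports the
    negated score as a pseudo-MFE.
    """

    name = "nussinov-maxpair (non-thermodynamic fallback)"
    _PAIR = {("G", "C"): 3.0, ("C", "G"): 3.0, ("A", "U"): 2.0,
             ("U", "A"): 2.0, ("G", "U"): 1.0, ("U", "G"): 1.0}
    MIN_LOOP = 3

    def fold(self, seq: str) -> tuple[str, float]:
        s = _check_fold_input(seq)
        n = len(s)
        if n < 2:
            return "." * n, 0.0
        best = [[0.0] * n for _ in range(n)]
        for span in range(self.MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                v = best[i][j - 1]
                for k in range(i, j - self.MIN_LOOP):
                    pair = self._PAIR.get((s[k], s[j]))
                    if pair is None:
                        continue
                    left = best[i][k - 1] if k > i else 0.0
                    inner = best[k + 1][j - 1]
                    v = max(v, left + pair + inner)
                best[i][j] = v
        structure = ["."] * n

        def traceback(i: int, j: int) -> None:
            while j > i + self.MIN_LOOP:
                if best[i][j] == best[i][j - 1]:
                    j -= 1
                    continue
                for k in range(i, j - self.MIN_LOOP):
                    pair = self._PAIR.get((s[k], s[j]))
                    if pair is None:
                        continue
                    left = best[i][k - 1] if k > i else 0.0
                    if abs(left + pair + best[k + 1][j - 1] - best[i][j]) < 1e-9:
                        structure[k], structure[j] = "(", ")"
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
                else:  # pragma: no cover - defensive
                    break

        traceback(0, n - 1)
        return "".join(structure), -best[0][n - 1]


_default: Folder | None = None


def default_folder() -> Folder:
    """ViennaRNA when importable, otherwise the built-in fallback."""
    global _default
    if _default is None:
        try:
            _default = ViennaFolder()
        except ImportError:  # pragma: no cover - environment-dependent
            _default = NussinovFolder()
    return _default


def fold(seq: str, folder: Folder | None = None) -> tuple[str, float]:
    """Dot-bracket structure and MFE (kcal/mol, <= 0) for a sequence."""
    return (folder or default_folder()).fold(seq)


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 if unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise InputError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise InputError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise InputError("unbalanced dot-bracket string")
    return pt
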