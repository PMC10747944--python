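"""Decompose SMILES strings into attribute tokens and count subset frequencies.

The model treats a SMILES string purely as text: an *attribute* is one
symbol, or a group of symbols that cannot be considered separately — a
bracket-atom block such as ``[N+]``, a two-character halogen ``Cl``/``Br``,
a two-digit ring closure ``%nn``, or otherwise a single character.  No
chemical perception (valence, aromaticity, canonical form) is performed.

Closing parentheses are merged with opening ones: ``)`` and ``(`` denote the
same structural attribute (a branch), so both map to the symbol ``(``.  Use
:func:`lex` when the raw lexemes are needed to reconstruct the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EmptyInputError, MalformedSmilesError, SubsetLabelError

SUBSET_LABELS = ("active_training", "passive_training", "calibration", "validation")

#: Two-character element symbols recognised outside bracket blocks.
TWO_CHAR_ELEMENTS = ("Cl", "Br")

_UNICODE_MINUS = "−"


def lex(smiles: str) -> list[str]:
    """Split a SMILES string into raw lexemes.

    Lexemes concatenate back to the input exactly (``"".join(lex(s)) == s``,
    after Unicode-minus normalisation).  Bracket blocks, ``Cl``, ``Br`` and
    ``%nn`` ring closures are single lexemes; every other character stands
    alone.

    Raises
    ------
    EmptyInputError
        If `smiles` is empty.
    MalformedSmilesError
        On unbalanced or nested ``[`` / ``]``.
    """
    if not smiles:
        raise EmptyInputError("cannot tokenize an empty SMILES string")
    s = smiles.replace(_UNICODE_MINUS, "-")
    out: list[str] = []
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch == "[":
            j = s.find("]", i + 1)
            if j == -1:
                raise MalformedSmilesError(f"unclosed '[' at position {i}: {smiles!r}")
            if "[" in s[i + 1 : j]:
                raise MalformedSmilesError(f"nested '[' at position {i}: {smiles!r}")
            out.append(s[i : j + 1])
            i = j + 1
        elif ch == "]":
            raise MalformedSmilesError(f"unmatched ']' at position {i}: {smiles!r}")
        elif ch == "%" and i + 2 < n and s[i + 1 : i + 3].isdigit():
            out.append(s[i : i + 3])
            i += 3
        elif s[i : i + 2] in TWO_CHAR_ELEMENTS:
            out.append(s[i : i + 2])
            i += 2
        else:
            out.append(ch)
            i += 1
    return out


def tokenize(smiles: str) -> list[str]:
    """Return the ordered list of attribute tokens of a SMILES string.

    Identical to :func:`lex` except that ``)`` is normalised to the
    attribute symbol ``(``.

    >>> tokenize("CC#CC")
    ['C', 'C', '#', 'C', 'C']
    >>> tokenize("c1ccccc1Cl")
    ['c', '1', 'c', 'c', 'c', 'c', 'c', '1', 'Cl']
    """
    return ["(" if t == ")" else t for t in lex(smiles)]


def detokenize(lexemes: Sequence[str]) -> str:
    """Reassemble raw lexemes (from :func:`lex`) into the original string."""
    return "".join(lexemes)


@dataclass
class TokenFrequencies:
    """Molecule-level token counts for one subset.

    ``counts[t]`` is the number of molecules in the subset that contain the
    token at least once — not the total number of occurrences.
    """

    counts: Counter = field(default_factory=Counter)
    subset_label: str = "active_training"
    n_molecules: int = 0

    def __post_init__(self) -> None:
        if self.subset_label not in SUBSET_LABELS:
            raise SubsetLabelError(f"unknown subset label {self.subset_label!r}")

    def __getitem__(self, token: str) -> int:
        return self.counts.get(token, 0)


def count_frequencies(
    molecules: Iterable[Sequence[str]], subset_label: str
) -> TokenFrequencies:
    """Count, per token, how many tokenized molecules contain it at least once."""
    counts: Counter = Counter()
    n = 0
    for tokens in molecules:
        n += 1
        counts.update(set(tokens))
    return TokenFrequencies(counts=counts, subset_label=subset_label, n_molecules=n)


def select_active_tokens(freq: TokenFrequencies, threshold: int) -> set[str]:
    """Select active tokens: frequency strictly above `threshold` in the active training set.

    Tokens not selected are *blocked*: their correlation weight is fixed at
    zero for the whole optimization.
    """
    if freq.subset_label != "active_training":
        raise SubsetLabelError(
            "active tokens must be selected on the active training set, "
            f"got {freq.subset_label!r}"
        )
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return {t for t, c in freq.counts.items() if c > threshold}
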