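"""Deterministic regex tokenization of SMILES strings.

Chemically meaningful multi-character units are kept atomic: bracket atoms
(``[C@@H]``, ``[nH+]``), two-letter elements (Cl, Br, Si, Se, ...), the
``%nn`` two-digit ring-closure form, stereo bond markers and ring digits.
Characters outside the inventory map to a reserved unknown token with a
warning rather than failing the whole molecule.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

MAX_TOKENS = 512

PAD, UNK = "<pad>", "<unk>"

_SMILES_PATTERN = re.compile(
    r"(\[[^\]]+\]"  # bracket atom, one token
    r"|Br|Cl|Si|Se|Na|Li|Mg|Ca|Al|Fe|Zn|As|Ag|Au|Te|Sn"
    r"|B|C|N|O|P|S|F|I"
    r"|b|c|n|o|p|s|se|te"
    r"|%\d{2}"  # two-digit ring closure
    r"|\d"
    r"|=|#|\+|-|\(|\)|/|\\|\.|@@|@|:|~|\*|\$"
    r")"
)


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(
    smiles: str, max_tokens: int = MAX_TOKENS, ligand_id: str | None = None
) -> TokenSequence:
    """Segment a SMILES string into chemical tokens.

    Raises :class:`TokenizationError` for empty input or sequences longer
    than ``max_tokens`` (the model's positional budget).
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    unknown: list[str] = []
    while pos < len(smiles):
        m = _SMILES_PATTERN.match(smiles, pos)
        if m:
            tokens.append(m.group(0))
            pos = m.end()
        else:
            unknown.append(smiles[pos])
            tokens.append(UNK)
            pos += 1
    if unknown:
        warnings.warn(
            f"unknown characters {sorted(set(unknown))} in SMILES "
            f"{smiles[:40]!r} mapped to {UNK}",
            stacklevel=2,
        )
    if len(tokens) > max_tokens:
        name = ligand_id or smiles[:40]
        raise TokenizationError(
            f"ligand {name!r}: {len(tokens)} tokens exceeds the "
            f"{max_tokens}-token limit"
        )
    return TokenSequence(tuple(tokens))


class Vocabulary:
    """Token <-> index map with reserved padding and unknown entries."""

    def __init__(self, tokens: list[str] | None = None) -> None:
        base = [PAD, UNK]
        extra = [t for t in (tokens or []) if t not in (PAD, UNK)]
        self._tokens = base + extra
        self._index = {t: i for i, t in enumerate(self._tokens)}

    @classmethod
    def from_corpus(cls, sequences: list[TokenSequence]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for seq in sequences:
            for t in seq.tokens:
                seen.setdefault(t, None)
        return cls(sorted(seen))

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def unk_id(self) -> int:
        return self._index[UNK]

    def encode(self, seq: TokenSequence) -> list[int]:
        unk = self.unk_id
        return [self._index.get(t, unk) for t in seq.tokens]

    def tokens(self) -> list[str]:
        return list(self._tokens)
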