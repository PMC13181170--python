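"""Content-addressed cache for frozen molecule embeddings.

When a nontrainable encoder supplies molecule representations, they never
change between epochs, so they are computed once per distinct SMILES and
reused.  The store is keyed by the SMILES string itself; an access counter
makes cache behaviour observable in tests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)


class EmbeddingCache:
    """Wraps a frozen ``encoder(smiles) -> vector`` with memoization."""

    def __init__(self, encoder: Callable[[str], np.ndarray]) -> None:
        self._encoder = encoder
        self._store: dict[str, np.ndarray] = {}
        self.encoder_calls = 0

    def get(self, smiles: str) -> np.ndarray:
        if smiles not in self._store:
            self.encoder_calls += 1
            self._store[smiles] = np.asarray(
                self._encoder(smiles), dtype=np.float64
            )
        return self._store[smiles]

    def get_many(self, smiles: list[str]) -> np.ndarray:
        return np.stack([self.get(s) for s in smiles])

    def __len__(self) -> int:
        return len(self._store)

    def save(self, path: str | Path) -> None:
        payload = {k: v.tolist() for k, v in self._store.items()}
        Path(path).write_text(json.dumps(payload))

    def load(self, path: str | Path) -> None:
        """Merge a persisted store; a corrupt file triggers a rebuild."""
        try:
            payload = json.loads(Path(path).read_text())
            for k, v in payload.items():
                self._store[k] = np.asarray(v, dtype=np.float64)
        except (json.JSONDecodeError, ValueError, TypeError):
            logger.warning("embedding store %s corrupt; rebuilding", path)
            self._store.clear()
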