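"""Position weight matrices: container, log-odds scanning, MEME-minimal I/O.

Motif occurrence in DMR sequences is scored with a plain log-odds PWM scanner
against a uniform 0.25 background: the score of a sequence is the maximum
summed log2-odds over all positions and both strands.  This is a deliberately
simple, self-contained scanner; the enrichment statistic built on top of it
(recovery-curve AUC and NES, see :mod:`epiretro.regulatory`) is where the
method lives.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MotifPwm", "scan_sequences", "read_meme_minimal", "write_meme_minimal"]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# floor on matrix probabilities so log-odds stay finite
_PSEUDO = 1e-3


@dataclass
class MotifPwm:
    """A motif: position-by-base probability matrix plus annotated TF genes."""

    motif_id: str
    matrix: np.ndarray                      # width x 4, rows sum to 1
    tf_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        p = np.clip(self.matrix, _PSEUDO, None)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / background)

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def sample_site(self, rng: np.random.Generator, min_score: float | None = None) -> str:
        """Draw one motif instance from the probability matrix.

        With ``min_score`` set, rejection-sample until the site's log-odds
        score reaches it (a bounded number of tries, then the consensus): a
        planted *functional* site must be recognizable by the scanner.
        """
        for _ in range(100):
            site = "".join(
                _ALPHABET[rng.choice(4, p=row / row.sum())] for row in self.matrix
            )
            if min_score is None or site_score(self, site) >= min_score:
                return site
        return self.consensus()


def _encode(seq: str) -> np.ndarray:
    return np.array([_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def _best_score(lom: np.ndarray, encoded: np.ndarray) -> float:
    w = lom.shape[0]
    n = encoded.size
    if n < w:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return -np.inf
    scores = lom[np.arange(w), windows[valid]].sum(axis=1)
    return float(scores.max())


def site_score(motif: MotifPwm, site: str, background: float = 0.25) -> float:
    """Log2-odds score of one ungapped site of exactly the motif's width."""
    lom = motif.log_odds(background)
    enc = _encode(site)
    if enc.size != motif.width or (enc < 0).any():
        raise ValueError("site must match the motif width over ACGT")
    return float(lom[np.arange(motif.width), enc].sum())


def scan_sequences(
    motif: MotifPwm, sequences: list[str], background: float = 0.25
) -> np.ndarray:
    """Max log2-odds score of ``motif`` in each sequence, both strands."""
    lom = motif.log_odds(background)
    scores = np.empty(len(sequences))
    for i, seq in enumerate(sequences):
        fwd = _best_score(lom, _encode(seq))
        rev = _best_score(lom, _encode(_revcomp(seq)))
        scores[i] = max(fwd, rev)
    return scores


def motif_hit_threshold(motif: MotifPwm, fraction_of_max: float = 0.8) -> float:
    """Score cutoff for calling a binding site: a fraction of the best possible
    log-odds score (in bits above background)."""
    lom = motif.log_odds()
    return fraction_of_max * lom.max(axis=1).sum()


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme_minimal(path_or_handle) -> list[MotifPwm]:
    """Read motifs from a MEME minimal-format file.

    TF gene annotations may be carried in the alternate motif name as a
    comma-separated list (``MOTIF id tf1,tf2``).
    """
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    motifs: list[MotifPwm] = []
    lines = iter(text.splitlines())
    for line in lines:
        if not line.startswith("MOTIF"):
            continue
        parts = line.split()
        motif_id = parts[1]
        tf_genes = tuple(parts[2].split(",")) if len(parts) > 2 else ()
        # seek the letter-probability header
        for header in lines:
            if header.strip().startswith("letter-probability"):
                break
        else:
            raise ValueError(f"motif {motif_id}: missing letter-probability matrix")
        m = re.search(r"w\s*=\s*(\d+)", header)
        if not m:
            raise ValueError(f"motif {motif_id}: cannot parse width from {header!r}")
        w = int(m.group(1))
        rows = []
        for _ in range(w):
            rows.append([float(x) for x in next(lines).split()[:4]])
        motifs.append(MotifPwm(motif_id, np.array(rows), tf_genes))
    return motifs


def write_meme_minimal(motifs: list[MotifPwm], path_or_handle) -> None:
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\n")
    buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for m in motifs:
        alt = ",".join(m.tf_genes)
        buf.write(f"MOTIF {m.motif_id}{(' ' + alt) if alt else ''}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
        for row in m.matrix:
            buf.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
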