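"""PSSM handling and the 230-attribute sliding-window feature encoding.

Each residue is encoded from two local windows centred on it: nine
residues of scaled PSSM log-odds (9 x 20 = 180 attributes) and five
residues of one-hot predicted secondary structure (5 x 3 = 15) plus
one-hot predicted dihedral cluster (5 x 7 = 35), for 230 attributes in
total.  Window positions falling outside the chain are padded with
all-zero sub-blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AA_ALPHABET",
    "PSSM_WINDOW",
    "UPSTREAM_WINDOW",
    "N_FEATURES",
    "PSSMProfile",
    "UpstreamPrediction",
    "PSSMParseError",
    "parse_pssm",
    "scale_pssm",
    "encode_ss",
    "encode_cluster",
    "encode_residue",
    "encode_chain",
]

#: Canonical internal amino-acid column order (alphabetical one-letter).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: PSSM window length (residues), centred on the predicted residue.
PSSM_WINDOW = 9
#: Secondary-structure / dihedral-cluster window length (residues).
UPSTREAM_WINDOW = 5
#: Total attribute count: 9*20 PSSM + 5*3 SS + 5*7 cluster.
N_FEATURES = PSSM_WINDOW * 20 + UPSTREAM_WINDOW * 3 + UPSTREAM_WINDOW * 7

_SS_BITS = {"H": (1, 0, 0), "E": (0, 1, 0), "C": (0, 0, 1)}
_N_CLUSTERS = 7


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass
class PSSMProfile:
    """A position-specific scoring matrix: L x 20 log-odds with the sequence.

    Columns follow :data:`AA_ALPHABET` order internally regardless of the
    column order of the source file.  ``scaled`` records whether the
    divide-by-ten scaling has been applied.
    """

    sequence: str
    scores: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must be an L x 20 matrix")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("PSSM row count must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def score(self, index: int, aa: str) -> float:
        """Score at 1-based residue ``index`` for amino-acid column ``aa``."""
        return float(self.scores[index - 1, AA_ALPHABET.index(aa)])


@dataclass
class UpstreamPrediction:
    """Per-residue predicted secondary structure (H/E/C) and dihedral cluster (0-6)."""

    ss: str
    clusters: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ss) != len(self.clusters):
            raise ValueError("ss and cluster sequences must have equal length")
        bad = set(self.ss) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary structure labels: {sorted(bad)}")
        if any(not (0 <= c < _N_CLUSTERS) for c in self.clusters):
            raise ValueError("cluster labels must be integers in 0..6")

    def __len__(self) -> int:
        return len(self.ss)


def parse_pssm(text: str) -> PSSMProfile:
    """Parse the log-odds block of a PSI-BLAST ASCII PSSM (`-out_ascii_pssm`).

    The first 20 columns after the residue number and letter are the
    log-odds scores; the trailing weighted-percentage block and footer
    statistics are ignored.  Column identities come from the header line
    and are remapped to the canonical alphabetical order, so differently
    ordered PSSM dialects produce identical profiles.
    """
    lines = text.splitlines()
    header_cols: list[str] | None = None
    header_at = -1
    for ln, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in AA_ALPHABET and len(t) == 1 for t in toks[:20]):
            header_cols = toks[:20]
            header_at = ln
            break
    if header_cols is None:
        raise PSSMParseError("no 20-column amino-acid header line found")
    if sorted(header_cols) != sorted(AA_ALPHABET):
        raise PSSMParseError("header does not list the 20 standard amino acids")

    order = [header_cols.index(a) for a in AA_ALPHABET]
    seq: list[str] = []
    rows: list[list[int]] = []
    expected = 1
    for ln in range(header_at + 1, len(lines)):
        toks = lines[ln].split()
        if not toks:
            if rows:
                break  # blank line terminates the matrix block
            continue
        if not toks[0].isdigit():
            break  # footer (lambda/K statistics)
        if len(toks) < 22:
            raise PSSMParseError(
                f"line {ln + 1}: expected residue number, letter and 20 scores, "
                f"got {len(toks)} fields")
        if int(toks[0]) != expected:
            raise PSSMParseError(f"line {ln + 1}: residue numbering broken "
                                 f"(expected {expected}, got {toks[0]})")
        aa = toks[1]
        if len(aa) != 1 or not aa.isalpha():
            raise PSSMParseError(f"line {ln + 1}: invalid residue letter {aa!r}")
        try:
            vals = [int(t) for t in toks[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {ln + 1}: non-integer score field") from exc
        seq.append(aa.upper())
        rows.append([vals[j] for j in order])
        expected += 1
    if not rows:
        raise PSSMParseError("no score rows found after the header")
    return PSSMProfile("".join(seq), np.array(rows, dtype=float))


def scale_pssm(profile: PSSMProfile) -> PSSMProfile:
    """Linearly scale log-odds by dividing by ten; no clipping is applied.

    Raw values typically fall in [-7, 7], so scaled values typically fall
    in [-0.7, 0.7], but values outside that range are passed through.
    """
    return replace(profile, scores=profile.scores / 10.0, scaled=True)


def encode_ss(label: str) -> np.ndarray:
    """One-hot SS encoding: H -> (1,0,0), E -> (0,1,0), C -> (0,0,1)."""
    try:
        return np.array(_SS_BITS[label], dtype=float)
    except KeyError:
        raise ValueError(f"unknown secondary structure label {label!r}") from None


def encode_cluster(cluster: int) -> np.ndarray:
    """One-hot encoding of a dihedral cluster id over seven binary attributes."""
    if not isinstance(cluster, (int, np.integer)) or not 0 <= cluster < _N_CLUSTERS:
        raise ValueError(f"cluster id must be an integer in 0..6, got {cluster!r}")
    bits = np.zeros(_N_CLUSTERS, dtype=float)
    bits[cluster] = 1.0
    return bits


def encode_residue(profile: PSSMProfile, upstream: UpstreamPrediction,
                   index: int) -> np.ndarray:
    """Encode 1-based residue ``index`` into the 230-attribute vector.

    Layout: window offsets -4..+4, 20 PSSM values each; then offsets
    -2..+2, 3 SS bits each; then offsets -2..+2, 7 cluster bits each.
    Out-of-chain window positions contribute all-zero sub-blocks.
    """
    length = len(profile)
    if len(upstream) != length:
        raise ValueError("profile and upstream prediction lengths differ")
    if not 1 <= index <= length:
        raise ValueError(f"residue index {index} outside chain of length {length}")
    half1 = PSSM_WINDOW // 2
    half2 = UPSTREAM_WINDOW // 2
    i0 = index - 1
    parts: list[np.ndarray] = []
    for off in range(-half1, half1 + 1):
        j = i0 + off
        parts.append(profile.scores[j] if 0 <= j < length else np.zeros(20))
    for off in range(-half2, half2 + 1):
        j = i0 + off
        parts.append(encode_ss(upstream.ss[j]) if 0 <= j < length else np.zeros(3))
    for off in range(-half2, half2 + 1):
        j = i0 + off
        parts.append(encode_cluster(upstream.clusters[j]) if 0 <= j < length
                     else np.zeros(_N_CLUSTERS))
    return np.concatenate(parts)


def encode_chain(profile: PSSMProfile,
                 upstream: UpstreamPrediction) -> np.ndarray:
    """Encode every residue of a chain; returns an L x 230 matrix."""
    return np.array([encode_residue(profile, upstream, i)
                     for i in range(1, len(profile) + 1)])
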