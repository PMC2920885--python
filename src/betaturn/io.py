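"""File formats: PDB backbones, ASCII PSSMs, FASTA, TSV tables.

Readers are deliberately strict about what the pipeline needs (N, CA
and C atoms of standard residues) and permissive about everything else.
Chains are split at breaks (consecutive CA-CA distance of 4.5 A or
more), and residues missing any backbone atom are dropped with a logged
warning, so downstream geometry never sees an incomplete residue.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1

from .annotation import CHAIN_BREAK_CUTOFF, CHANNELS, BackboneStructure, Residue
from .features import AA_ALPHABET, PSSMProfile

logger = logging.getLogger("betaturn")

__all__ = [
    "read_pdb_backbones",
    "write_pdb_backbone",
    "read_fasta",
    "write_fasta",
    "write_pssm",
    "read_prediction_table",
    "write_prediction_table",
    "write_annotation_table",
    "write_metrics_tsv",
]


def _split_on_breaks(chain_id: str, residues: list[Residue]) -> list[BackboneStructure]:
    """Split a residue run wherever consecutive CA atoms are too far apart."""
    structures: list[BackboneStructure] = []
    segment: list[Residue] = []
    for r in residues:
        if segment and np.linalg.norm(r.ca - segment[-1].ca) >= CHAIN_BREAK_CUTOFF:
            structures.append(BackboneStructure(chain_id=chain_id, residues=segment))
            segment = []
        segment.append(r)
    if segment:
        structures.append(BackboneStructure(chain_id=chain_id, residues=segment))
    if len(structures) > 1:
        logger.warning("chain %s split into %d segments at chain breaks",
                       chain_id, len(structures))
    return structures


def read_pdb_backbones(path) -> list[BackboneStructure]:
    """Read backbone chains from a PDB file's ATOM records.

    Returns one structure per unbroken chain segment.  Only standard
    amino-acid residues with all of N, CA and C present are kept; for
    disordered atoms the first alternate location is used.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())
    out: list[BackboneStructure] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            if not all(a in res for a in ("N", "CA", "C")):
                logger.warning("%s chain %s residue %s lacks backbone atoms; dropped",
                               path, chain.id, res.id[1])
                continue
            aa = protein_letters_3to1.get(res.get_resname(), "X")
            residues.append(Residue(
                index=res.id[1], aa=aa,
                n=np.array(res["N"].get_coord(), dtype=float),
                ca=np.array(res["CA"].get_coord(), dtype=float),
                c=np.array(res["C"].get_coord(), dtype=float)))
        if residues:
            out.extend(_split_on_breaks(chain.id, residues))
    return out


_AA_1TO3 = {v: k for k, v in protein_letters_3to1.items()}


def write_pdb_backbone(structure: BackboneStructure, path) -> None:
    """Write N/CA/C ATOM records in fixed-column PDB format."""
    serial = 1
    with open(path, "w") as fh:
        for r in structure.residues:
            res3 = _AA_1TO3.get(r.aa, "ALA")
            for name, coord in (("N", r.n), ("CA", r.ca), ("C", r.c)):
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s} {res3:3s} {structure.chain_id:1s}"
                    f"{r.index:4d}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n")
                serial += 1
        fh.write("TER\nEND\n")


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by the parser.

    Emits the header comment, the 20-letter column header and one row
    per residue with integer log-odds; the weighted-percentage block is
    written as zeros for layout fidelity.
    """
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        fh.write(" " * 11 + "".join(f"{a:>3s}" for a in AA_ALPHABET)
                 + "".join(f"{a:>4s}" for a in AA_ALPHABET) + "\n")
        for i, aa in enumerate(profile.sequence):
            scores = "".join(f"{int(round(v)):3d}" for v in profile.scores[i])
            pcts = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa}    {scores} {pcts}  0.00 0.00\n")
        fh.write("\n")


_TABLE_HEADER = ("aa", "index", "turn", "I", "II", "IV", "VIII", "NS")


def write_prediction_table(sequence: str, channels: dict[str, np.ndarray],
                           path_or_handle, index_offset: int = 1) -> None:
    """Write the per-residue prediction table.

    Whitespace-delimited columns: one-letter amino acid, 1-based residue
    number, then the six 0/1 channels in the order turn, I, II, IV,
    VIII, NS.
    """
    lengths = {len(channels[ch]) for ch in CHANNELS}
    if lengths != {len(sequence)}:
        raise ValueError("channel lengths do not match the sequence")
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("# " + " ".join(_TABLE_HEADER) + "\n")
        for i, aa in enumerate(sequence):
            bits = " ".join(str(int(channels[ch][i])) for ch in CHANNELS)
            fh.write(f"{aa} {i + index_offset} {bits}\n")
    finally:
        if own:
            fh.close()


def read_prediction_table(path) -> tuple[str, dict[str, np.ndarray]]:
    """Inverse of :func:`write_prediction_table`."""
    seq: list[str] = []
    cols: dict[str, list[int]] = {ch: [] for ch in CHANNELS}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 8:
            raise ValueError(f"{path}: expected 8 columns, got {len(toks)}")
        seq.append(toks[0])
        for ch, tok in zip(CHANNELS, toks[2:]):
            if tok not in ("0", "1"):
                raise ValueError(f"{path}: non-binary prediction value {tok!r}")
            cols[ch].append(int(tok))
    return "".join(seq), {ch: np.array(v, dtype=np.uint8) for ch, v in cols.items()}


def write_annotation_table(structure: BackboneStructure, labels,
                           turns, path) -> None:
    """Write geometric annotation: the label table plus the turn list."""
    with open(path, "w") as fh:
        fh.write("# index aa turn I II IV VIII NS\n")
        for i, r in enumerate(structure.residues):
            bits = "\t".join(str(int(labels[ch][i])) for ch in CHANNELS)
            fh.write(f"{r.index}\t{r.aa}\t{bits}\n")
        for t in turns:
            fh.write(f"# TURN\t{t.start}\t{t.type}\n")


def write_metrics_tsv(reports: dict[str, object], path) -> None:
    """Write per-channel metric reports as TSV ('NA' for undefined metrics)."""
    metric_names = ("q_total", "sensitivity", "specificity", "mcc",
                    "q_pred", "s_score", "auc")
    with open(path, "w") as fh:
        fh.write("channel\t" + "\t".join(metric_names) + "\n")
        for ch, rep in reports.items():
            d = rep.as_dict()
            vals = []
            for m in metric_names:
                v = d[m]
                if v is None:
                    vals.append("NA")
                elif m in ("mcc", "auc"):
                    vals.append(f"{v:.2f}")
                else:
                    vals.append(f"{v:.1f}")
            fh.write(ch + "\t" + "\t".join(vals) + "\n")
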