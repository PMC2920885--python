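"""Self-contained synthetic fixtures: backbones, planted turns, PSSMs.

Everything the pipeline consumes can be generated here without external
downloads: poly-alanine-like backbones built from prescribed (phi, psi)
by natural-extension-reference-frame (NeRF) placement with standard bond
geometry, chains with beta-turns of known type planted at chosen
positions, class-informative synthetic PSSMs, and noisy stand-ins for an
upstream secondary-structure/dihedral predictor.

Ground truth is always defined by re-annotating the built coordinates
with the geometric turn rules, never by the plan itself, so the builder
and the annotator cannot silently disagree: the generator raises if a
planted turn is not recovered.

What the generator emulates — and what it does not: turn-conditioned
mean shifts in PSSM columns stand in for evolutionary conservation
signal; label noise in the upstream predictions stands in for an
imperfect predictor.  There is no sequence-structure covariation, no
side-chain or proline-specific geometry, and no overlapping-turn
statistics matching real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    IDEAL_TURN_ANGLES,
    BackboneStructure,
    Residue,
    ResidueLabels,
    assign_beta_turns,
    labels_from_turns,
    phi_psi,
)
from .features import AA_ALPHABET, PSSMProfile, UpstreamPrediction
from .upstream import DEFAULT_CLUSTER_MODEL, assign_clusters

__all__ = [
    "GeometryDefaults",
    "TurnPlan",
    "GenerationError",
    "build_backbone",
    "make_turn_chain",
    "simulate_pssm",
    "corrupt_upstream",
    "make_corpus",
    "Corpus",
    "SyntheticChain",
    "EXTENDED_ANGLES",
    "TURN_SIGNAL_COLUMNS",
]

#: Flanking-region (phi, psi) used outside planted turns: an extended
#: conformation whose Calpha(i)-Calpha(i+3) separation is ~10 A, safely
#: above the turn cutoff.
EXTENDED_ANGLES = (-120.0, 120.0)

#: PSSM columns receiving the turn-conditioned mean shift: the classic
#: turn-favouring residues Asn, Asp, Gly, Pro.
TURN_SIGNAL_COLUMNS = tuple(AA_ALPHABET.index(a) for a in "NDGP")


class GenerationError(RuntimeError):
    """A requested synthetic construction is geometrically unrealisable."""


@dataclass(frozen=True)
class GeometryDefaults:
    """Standard trans-peptide backbone internal coordinates.

    Bond lengths in Angstrom, bond angles in degrees; the peptide
    torsion omega is fixed trans (180 degrees).
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    n_ca_c: float = 111.0
    ca_c_n: float = 117.2
    c_n_ca: float = 121.7
    omega: float = 180.0


@dataclass
class TurnPlan:
    """Blueprint for a chain with turns of known type at known positions."""

    length: int
    turns: list[tuple[int, str]] = field(default_factory=list)
    flank: tuple[float, float] = EXTENDED_ANGLES

    def __post_init__(self) -> None:
        for start, ttype in self.turns:
            if ttype not in IDEAL_TURN_ANGLES and ttype != "IV":
                raise ValueError(f"cannot plant unknown turn type {ttype!r}")
            if not 1 <= start <= self.length - 3:
                raise ValueError(f"turn at {start} does not fit in length {self.length}")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, angle(b,c,d) and
    torsion(a,b,c,d) as given (degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(dihedrals, geometry: GeometryDefaults | None = None,
                   chain_id: str = "A", sequence: str | None = None) -> BackboneStructure:
    """Build N/CA/C coordinates for a chain from per-residue (phi, psi).

    ``dihedrals`` lists one (phi, psi) pair per residue; phi of the first
    and psi of the last residue are never used and may be None.  Peptide
    bonds are ideal trans.  The construction round-trips: recomputing
    phi/psi from the built coordinates reproduces the prescription to
    well under half a degree.
    """
    geo = geometry or GeometryDefaults()
    dihedrals = list(dihedrals)
    L = len(dihedrals)
    if L < 1:
        raise ValueError("need at least one residue")
    seq = sequence or "A" * L
    if len(seq) != L:
        raise ValueError("sequence length must match dihedral list length")

    # first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([geo.n_ca, 0.0, 0.0])
    ang = np.radians(geo.n_ca_c)
    c0 = ca0 + geo.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms = [(n0, ca0, c0)]

    for k in range(1, L):
        n_prev, ca_prev, c_prev = atoms[-1]
        psi_prev = dihedrals[k - 1][1]
        phi_k = dihedrals[k][0]
        if psi_prev is None or phi_k is None:
            raise ValueError(f"interior residue {k} requires defined psi({k - 1})/phi({k})")
        n_k = _place_atom(n_prev, ca_prev, c_prev, geo.c_n, geo.ca_c_n, psi_prev)
        ca_k = _place_atom(ca_prev, c_prev, n_k, geo.n_ca, geo.c_n_ca, geo.omega)
        c_k = _place_atom(c_prev, n_k, ca_k, geo.ca_c, geo.n_ca_c, phi_k)
        atoms.append((n_k, ca_k, c_k))

    residues = [Residue(index=i + 1, aa=seq[i], n=n, ca=ca, c=c)
                for i, (n, ca, c) in enumerate(atoms)]
    return BackboneStructure(chain_id=chain_id, residues=residues)


#: Central-residue angles used to plant catch-all (type IV) turns: a
#: compact conformation (end-CA separation ~6.4 A with extended flanks)
#: that matches no specific type even under the planting jitter.  The
#: tabulated *average* type-IV angles are not used because, with ideal
#: trans peptides and extended flanks, they place the end CA atoms just
#: outside the 7 A cutoff.
_IV_PLANT_ANGLES = (-100.0, 10.0, -100.0, 10.0)


def _plant_angles(plan: TurnPlan, rng: np.random.Generator, jitter: float):
    """Per-residue (phi, psi) realising the plan, plus the in-turn mask."""
    angles = [list(plan.flank) for _ in range(plan.length)]
    in_turn = np.zeros(plan.length, dtype=bool)
    for start, ttype in plan.turns:
        ideal = _IV_PLANT_ANGLES if ttype == "IV" else IDEAL_TURN_ANGLES[ttype]
        phi1, psi1, phi2, psi2 = ideal
        for off, (phi, psi) in zip((1, 2), ((phi1, psi1), (phi2, psi2))):
            pos = start - 1 + off  # 0-based index of residue i+off
            target = [phi + rng.uniform(-jitter, jitter),
                      psi + rng.uniform(-jitter, jitter)]
            if in_turn[pos] and not np.allclose(angles[pos], target,
                                                atol=2 * jitter + 10):
                raise GenerationError(
                    f"overlapping turns prescribe conflicting angles at residue {pos + 1}")
            angles[pos] = target
        in_turn[start - 1:start + 3] = True
    return angles, in_turn


def make_turn_chain(plan: TurnPlan, seed: int = 0,
                    jitter: float = 3.0, sequence: str | None = None):
    """Build a chain realising a turn plan, with self-consistent labels.

    Residues i+1 and i+2 of each planted turn get the type's ideal
    angles plus a small seeded jitter (uniform, at most ``jitter`` <= 5
    degrees); all other residues take the plan's flanking angles.
    Ground truth comes from re-annotating the built structure; a
    :class:`GenerationError` is raised if any planted turn is not
    recovered with its planted type.  Planting type IV uses the
    tabulated average catch-all conformation.

    Returns ``(structure, labels, true_ss, true_angles)`` where true_ss
    marks planted turn residues 'C' and flanks 'E'.
    """
    if not 0 <= jitter <= 5.0:
        raise ValueError("jitter must be in [0, 5] degrees")
    rng = np.random.default_rng(seed)
    angles, in_turn = _plant_angles(plan, rng, jitter)
    structure = build_backbone(angles, sequence=sequence)
    turns = assign_beta_turns(structure, helix_mask=np.zeros(plan.length, dtype=int))
    recovered = {(t.start, t.type) for t in turns}
    for start, ttype in plan.turns:
        if (start, ttype) not in recovered:
            raise GenerationError(
                f"planted type-{ttype} turn at {start} was not recovered by annotation "
                f"(got {sorted(recovered)})")
    labels = labels_from_turns(turns, plan.length)
    true_ss = "".join("C" if in_turn[i] else "E" for i in range(plan.length))
    true_angles = phi_psi(structure)
    return structure, labels, true_ss, true_angles


def simulate_pssm(labels: ResidueLabels, signal: float = 5.0,
                  seed: int = 0, sequence: str | None = None) -> PSSMProfile:
    """Synthetic integer PSSM whose columns shift with turn membership.

    Background scores are integer-rounded draws from a zero-mean normal
    (sd 2.5) truncated to [-7, 7].  Residues inside turns receive a
    ``signal`` mean shift on the designated turn-favouring columns
    (N/D/G/P) before rounding; with signal 0 the matrix carries no class
    information.
    """
    if signal < 0:
        raise ValueError("signal must be non-negative")
    rng = np.random.default_rng(seed)
    L = len(labels)
    raw = np.clip(rng.normal(0.0, 2.5, size=(L, 20)), -7, 7)
    shift = np.zeros((L, 20))
    shift[np.asarray(labels["turn"], dtype=bool)[:, None]
          & np.isin(np.arange(20), TURN_SIGNAL_COLUMNS)[None, :]] = signal
    scores = np.rint(raw + shift)
    seq = sequence or "".join(rng.choice(list(AA_ALPHABET), size=L))
    return PSSMProfile(sequence=seq, scores=scores)


def corrupt_upstream(true_ss: str, true_clusters, error_rate: float,
                     seed: int = 0) -> UpstreamPrediction:
    """Emulate an imperfect upstream predictor by random label substitution.

    Each residue's SS label and cluster label are independently replaced
    by a uniformly chosen *different* label with probability
    ``error_rate``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ss_states = "HEC"
    ss_out = []
    for lab in true_ss:
        if rng.random() < error_rate:
            ss_out.append(rng.choice([s for s in ss_states if s != lab]))
        else:
            ss_out.append(lab)
    cl_out = []
    for lab in true_clusters:
        if rng.random() < error_rate:
            cl_out.append(int(rng.choice([c for c in range(7) if c != lab])))
        else:
            cl_out.append(int(lab))
    return UpstreamPrediction(ss="".join(ss_out), clusters=cl_out)


@dataclass
class SyntheticChain:
    """One generated chain with everything the pipeline needs."""

    chain_id: str
    structure: BackboneStructure
    labels: ResidueLabels
    profile: PSSMProfile        # raw (unscaled) synthetic PSSM
    upstream: UpstreamPrediction
    true_ss: str
    true_angles: list


@dataclass
class Corpus:
    """A labelled synthetic corpus: the unit of training and evaluation."""

    chains: list[SyntheticChain]
    seed: int

    def __len__(self) -> int:
        return len(self.chains)


#: Relative frequencies of planted turn types, following the observed
#: distribution of turn-type residues in non-redundant chain sets
#: (I and IV dominant, II less common, VIII and the NS group rare).
#: II' stands in for the miscellaneous NS group (the mirror and VI
#: types); it is the member of that group that plants most cleanly with
#: ideal trans peptides.
_TYPE_WEIGHTS = {"I": 9.3, "II": 3.8, "IV_like": 9.4, "VIII": 2.7, "II'": 2.4}


def _plant_type(rng: np.random.Generator) -> str:
    names = list(_TYPE_WEIGHTS)
    w = np.array([_TYPE_WEIGHTS[n] for n in names])
    return str(rng.choice(names, p=w / w.sum()))


def make_corpus(n_chains: int = 50, length_range: tuple[int, int] = (30, 60),
                turn_density: float = 0.25, signal: float = 5.0,
                upstream_error: float = 0.1, seed: int = 0,
                informative_upstream: bool = True) -> Corpus:
    """Generate a reproducible end-to-end training corpus.

    ``turn_density`` is the target fraction of residues inside turns
    (about a quarter of residues sit in beta-turns in real chain sets).
    ``signal`` is the PSSM column shift for turn residues and
    ``upstream_error`` the label-noise rate of the simulated upstream
    predictor.  With ``informative_upstream=False`` the upstream labels
    are drawn uniformly at random instead of from the true geometry,
    which (together with signal 0) yields a corpus carrying no class
    signal at all.  Per-chain seeds derive from the master seed.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be positive")
    if not 0.0 <= turn_density <= 0.5:
        raise ValueError("turn_density must be in [0, 0.5]")
    if length_range[0] < 8 or length_range[1] < length_range[0]:
        raise ValueError("invalid length range")
    master = np.random.default_rng(seed)
    chains: list[SyntheticChain] = []
    for ci in range(n_chains):
        sub = np.random.default_rng(master.integers(2 ** 31))
        L = int(sub.integers(length_range[0], length_range[1] + 1))
        n_turns = int(round(turn_density * L / 4))
        # sample non-overlapping starts with a >= 1 residue gap between
        # windows so planted prescriptions never collide
        starts: list[int] = []
        candidates = list(range(2, L - 4))
        sub.shuffle(candidates)
        for s in candidates:
            if len(starts) == n_turns:
                break
            if all(abs(s - s2) >= 5 for s2 in starts):
                starts.append(s)
        plan = TurnPlan(length=L, turns=[
            (s, "IV" if (t := _plant_type(sub)) == "IV_like" else t)
            for s in sorted(starts)])
        structure, labels, true_ss, true_angles = make_turn_chain(
            plan, seed=int(sub.integers(2 ** 31)))
        pssm_seed = int(sub.integers(2 ** 31))
        profile = simulate_pssm(labels, signal=signal, seed=pssm_seed)
        if informative_upstream:
            true_clusters = assign_clusters(true_angles, DEFAULT_CLUSTER_MODEL)
            upstream_pred = corrupt_upstream(true_ss, true_clusters,
                                             upstream_error,
                                             seed=int(sub.integers(2 ** 31)))
        else:
            urng = np.random.default_rng(int(sub.integers(2 ** 31)))
            upstream_pred = UpstreamPrediction(
                ss="".join(urng.choice(list("HEC"), size=L)),
                clusters=[int(c) for c in urng.integers(0, 7, size=L)])
        chains.append(SyntheticChain(
            chain_id=f"syn{ci:04d}", structure=structure, labels=labels,
            profile=profile, upstream=upstream_pred, true_ss=true_ss,
            true_angles=true_angles))
    return Corpus(chains=chains, seed=seed)
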