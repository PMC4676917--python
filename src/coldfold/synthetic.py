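"""Synthetic inputs with known ground truth.

Every pipeline stage is exercised on generated data whose truth is
recorded alongside it, so recovery tests are exact (network pipeline)
or statistical with a known target (thermogram fits):

* :func:`generate_thermogram` — two-state CD traces with both cold and
  heat transitions, linear baselines and additive Gaussian noise.
* :func:`generate_trajectory` — multi-model PDB "trajectories" of
  poly-alanine point residues with planted contact persistences that
  are achieved *exactly* by construction.
* :func:`generate_alignment` — orthologue-style FASTA alignments with
  charged residues planted in chosen columns.

The generators make geometric/statistical stand-ins, not physics: no
force field, no realistic CD band shapes — just the features the
downstream analyses consume.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fitting import Baseline, model_signal
from .thermo import CELSIUS_OFFSET, NoColdTransitionError, StabilityParams, cold_denaturation_temp
from .thermogram import Thermogram

__all__ = [
    "ThermogramSpec",
    "TrajectorySpec",
    "InfeasibleGeometryError",
    "generate_thermogram",
    "generate_trajectory",
    "write_trajectory_pdb",
    "generate_alignment",
]

# default synthetic baselines: plausible loss of 222 nm helicity signal
DEFAULT_BASELINE_FOLDED = Baseline(-10.0, 0.01)
DEFAULT_BASELINE_UNFOLDED = Baseline(-3.0, 0.02)

# planted-contact placement margins, nm: far enough from the 0.6 nm
# threshold that floating point cannot flip a classification
CONTACT_NM = 0.55
APART_NM = 0.85
MIN_SEPARATION_NM = 0.8
BACKGROUND_SPACING_NM = 2.0


class InfeasibleGeometryError(ValueError):
    """Planted edges cannot be embedded within the separation margins."""


@dataclass(frozen=True)
class ThermogramSpec:
    """Recipe for one synthetic thermogram with known truth."""

    params: StabilityParams
    baseline_folded: Baseline = DEFAULT_BASELINE_FOLDED
    baseline_unfolded: Baseline = DEFAULT_BASELINE_UNFOLDED
    T_range: tuple[float, float] = (0.0, 80.0)
    step: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.T_range
        if not lo < hi:
            raise ValueError("T_range must satisfy lo < hi")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_thermogram(spec: ThermogramSpec, label: str = "synthetic") -> tuple[Thermogram, dict]:
    """Simulate a CD thermogram; returns (data, truth record).

    The noiseless signal is exactly :func:`~coldfold.fitting.model_signal`
    evaluated on the temperature grid; Gaussian noise of sd ``noise_sd``
    (mdeg) is added with a seeded generator, so output is deterministic
    per seed.  Warns if the truth's cold transition lies below the
    simulated range (the cold arm would not be visible).
    """
    import warnings

    lo, hi = spec.T_range
    T = np.arange(lo, hi + 0.5 * spec.step, spec.step)
    clean = model_signal(T, spec.params, spec.baseline_folded, spec.baseline_unfolded)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=T.size) if spec.noise_sd > 0 else 0.0
    truth = {
        "dH_kcal_mol": spec.params.dH,
        "dCp_kcal_K_mol": spec.params.dCp,
        "Tm_C": spec.params.Tm_celsius,
        "baseline_folded": [spec.baseline_folded.intercept, spec.baseline_folded.slope],
        "baseline_unfolded": [spec.baseline_unfolded.intercept, spec.baseline_unfolded.slope],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    try:
        tc = cold_denaturation_temp(spec.params) - CELSIUS_OFFSET
        truth["Tc_C"] = tc
        if tc < lo:
            warnings.warn(f"true Tc = {tc:.1f} C below simulated range start {lo} C; "
                          "cold arm not visible", stacklevel=2)
    except NoColdTransitionError:
        truth["Tc_C"] = None
    return Thermogram(T, clean + noise, label=label), truth


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for a toy multi-model PDB trajectory with planted contacts."""

    n_residues: int
    n_frames: int
    planted_edges: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j), float(p)) for i, j, p in self.planted_edges))
        for i, j, p in self.planted_edges:
            if not (1 <= i < j <= self.n_residues):
                raise ValueError(f"planted edge ({i}, {j}) outside residue range")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"target persistence {p} outside [0, 1]")


def _edge_schedule(spec: TrajectorySpec) -> dict[tuple[int, int], int]:
    """Contact-frame count per planted edge: round(p * n_frames).

    Edges are "on" in a prefix of the frame order (frames 0..k-1), which
    keeps the number of distinct per-frame configurations small while
    making the achieved persistence an exact count.
    """
    return {(i, j): int(round(p * spec.n_frames)) for i, j, p in spec.planted_edges}


def _embed_configuration(spec: TrajectorySpec, active: frozenset, rng) -> np.ndarray:
    """Coordinates (nm) for one active-edge configuration.

    Planted-active pairs sit at CONTACT_NM, planted-inactive at APART_NM,
    and every other pair is pushed beyond MIN_SEPARATION_NM.  Solved by
    stress minimisation from a jittered grid start and verified against
    the margins; failure to satisfy them raises InfeasibleGeometryError.
    """
    n = spec.n_residues
    planted = {(i - 1, j - 1): (i, j) in active or (j, i) in active
               for i, j, _ in spec.planted_edges}

    # grid start with deterministic jitter
    side = int(np.ceil(n ** (1 / 3)))
    base = np.array([(x, y, z) for x in range(side) for y in range(side)
                     for z in range(side)][:n], dtype=float) * BACKGROUND_SPACING_NM
    x0 = (base + rng.normal(0, 0.05, base.shape)).ravel()

    pairs_all = list(itertools.combinations(range(n), 2))

    def stress(x):
        pos = x.reshape(n, 3)
        s = 0.0
        for a, b in pairs_all:
            d = np.linalg.norm(pos[a] - pos[b])
            if (a, b) in planted:
                target = CONTACT_NM if planted[(a, b)] else APART_NM
                s += (d - target) ** 2
            elif d < MIN_SEPARATION_NM + 0.15:
                s += (d - (MIN_SEPARATION_NM + 0.15)) ** 2
        return s

    sol = minimize(stress, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14})
    pos = sol.x.reshape(n, 3)

    # verify margins
    for a, b in pairs_all:
        d = np.linalg.norm(pos[a] - pos[b])
        if (a, b) in planted:
            if planted[(a, b)]:
                if not d < 0.58:
                    raise InfeasibleGeometryError(
                        f"active pair {(a + 1, b + 1)} embedded at {d:.3f} nm (need < 0.58)")
            elif not d >= MIN_SEPARATION_NM:
                raise InfeasibleGeometryError(
                    f"inactive planted pair {(a + 1, b + 1)} at {d:.3f} nm (need >= {MIN_SEPARATION_NM})")
        elif not d >= MIN_SEPARATION_NM:
            raise InfeasibleGeometryError(
                f"background pair {(a + 1, b + 1)} at {d:.3f} nm (need >= {MIN_SEPARATION_NM})")
    return pos


def generate_trajectory(spec: TrajectorySpec) -> tuple[list[np.ndarray], dict]:
    """Per-frame residue coordinates (nm) realising the planted contacts.

    Returns (frames, truth); ``frames[f][r]`` is the side-chain control
    point of residue r+1 in frame f.  Each planted edge (i, j, p) is
    below 0.6 nm in exactly round(p * n_frames) frames and at least
    0.8 nm away otherwise; all non-planted pairs stay >= 0.8 nm in every
    frame, so downstream persistence equals the plant exactly.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = _edge_schedule(spec)
    # configuration of frame f = set of edges still "on" at f (prefix schedules)
    frame_configs = []
    for f in range(spec.n_frames):
        frame_configs.append(frozenset(e for e, k in schedule.items() if f < k))
    cache: dict[frozenset, np.ndarray] = {}
    frames = []
    for cfg in frame_configs:
        if cfg not in cache:
            cache[cfg] = _embed_configuration(spec, cfg, rng)
        frames.append(cache[cfg])
    truth = {
        "n_residues": spec.n_residues,
        "n_frames": spec.n_frames,
        "planted_edges": [list(e) for e in spec.planted_edges],
        "contact_frames": {f"{i}-{j}": schedule[(i, j)] for i, j, _ in spec.planted_edges},
        "expected_persistence": {f"{i}-{j}": schedule[(i, j)] / spec.n_frames
                                 for i, j, _ in spec.planted_edges},
        "seed": spec.seed,
    }
    return frames, truth


def write_trajectory_pdb(frames: list[np.ndarray], path) -> None:
    """Write frames as a multi-model poly-alanine PDB.

    Each residue gets N, CA and CB atoms; CB carries the control point
    (the only side-chain heavy atom of alanine), so the minimum
    side-chain distance between two residues is the planted CB–CB
    distance.  Coordinates are converted nm -> angstrom.  Output is
    byte-deterministic for given frames.
    """
    n_res = frames[0].shape[0]
    offsets = {"N": np.array([-1.2, -0.8, 0.0]), "CA": np.array([-1.0, 0.3, 0.0]),
               "CB": np.array([0.0, 0.0, 0.0])}
    lines: list[str] = []
    for f, pos in enumerate(frames, start=1):
        lines.append(f"MODEL     {f:>4}")
        serial = 1
        for r in range(n_res):
            center = pos[r] * 10.0  # nm -> angstrom
            for name in ("N", "CA", "CB"):
                x, y, z = center + offsets[name]
                # strict fixed-width PDB columns: name 13-16, resName 18-20,
                # chain 22, resSeq 23-26, coords 31-54, element 77-78
                lines.append(
                    f"ATOM  {serial:>5}  {name:<3} ALA A{r + 1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{name[0]:>2}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


NEUTRAL_ALPHABET = "ACFGILMNPQSTVWY"  # no D/E/K/R (and no H)


def generate_alignment(n_sequences: int, length: int, planted_charge_columns,
                       seed: int = 0, reference_id: str = "REF") -> tuple[str, dict]:
    """FASTA alignment text with charges planted in chosen columns.

    The background is drawn from a neutral alphabet (no D/E/K/R/H).  At
    each planted column exactly one sequence — chosen by the seeded rng —
    carries a charged residue (D, E, K or R).  ``planted_charge_columns``
    may be an iterable of 1-based columns, or a mapping column -> residue
    to control the planted identity.  Sequence 0 is the reference, named
    ``reference_id``; it is gap-free so alignment columns equal reference
    positions.

    Returns (fasta_text, truth) where truth records the planted columns,
    carriers and charge classes.
    """
    rng = np.random.default_rng(seed)
    if isinstance(planted_charge_columns, dict):
        planted = {int(c): r for c, r in planted_charge_columns.items()}
    else:
        planted = {int(c): None for c in planted_charge_columns}
    for col in planted:
        if not 1 <= col <= length:
            raise ValueError(f"planted column {col} outside 1..{length}")

    alphabet = np.array(list(NEUTRAL_ALPHABET))
    seqs = rng.choice(alphabet, size=(n_sequences, length))
    truth_cols: dict[int, dict] = {}
    for col, res in sorted(planted.items()):
        carrier = int(rng.integers(n_sequences))
        residue = res if res is not None else str(rng.choice(list("DEKR")))
        seqs[carrier, col - 1] = residue
        truth_cols[col] = {
            "carrier": carrier,
            "residue": residue,
            "charge_class": "acidic" if residue in "DE" else "basic",
        }
    names = [reference_id] + [f"ORTHO{i}" for i in range(1, n_sequences)]
    fasta = "".join(f">{names[s]}\n{''.join(seqs[s])}\n" for s in range(n_sequences))
    truth = {
        "planted_columns": sorted(truth_cols),
        "columns": {str(c): v for c, v in truth_cols.items()},
        "reference_id": reference_id,
        "seed": seed,
    }
    return fasta, truth


def dump_truth(truth: dict, path) -> None:
    """Write a generator truth record as a JSON side-file."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
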