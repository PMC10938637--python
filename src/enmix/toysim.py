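"""Self-contained toy systems with known answers.

Provides the three ingredients needed to exercise the whole pipeline
without any external data:

* deterministic fixture structures (compact vs extended bead chains);
* a Metropolis Monte Carlo sampler for λ-parameterized harmonic
  Hamiltonians that emits per-window work samples in the same layout the
  estimators consume;
* analytic Gaussian free-energy oracles (independent 1-D oscillators and
  Crooks-consistent synthetic work pairs).

Monte Carlo rather than dynamics: only equilibrium ensembles matter for
BAR/TI input, and Metropolis with symmetric Gaussian single-bead proposals
satisfies detailed balance exactly with no integrator artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cg_structures import Bead, BeadStructure
from .constants import DEFAULT_TEMPERATURE, kt
from .errors import (
    ParameterError,
    UnboundedSystemError,
    UnsupportedSystemError,
    ValidationError,
)
from .free_energy import WindowWorkData
from .perturbation import (
    LambdaSchedule,
    PerturbedTerm,
    PerturbedTopology,
    restraint_dhdl,
    restraint_energy,
)
from .topology import AtomRecord, BondedTerm, Topology

#: sampling interval attached to emitted time stamps, ps
SAMPLE_SPACING_PS = 50.0


@dataclass
class SamplerConfig:
    n_steps: int = 20000
    burn_in: int = 2000
    stride: int = 2
    step_size: float | None = None  # nm; None -> auto-tuned during burn-in
    seed: int = 0

    def __post_init__(self):
        if self.n_steps <= self.burn_in:
            raise ParameterError("n_steps must exceed burn_in")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")


@dataclass(frozen=True)
class Oscillator1D:
    """One independent 1-D degree of freedom with λ-interpolated k and b0."""

    k_A: float
    k_B: float
    b0_A: float = 0.0
    b0_B: float = 0.0

    def k(self, lam: float) -> float:
        return (1.0 - lam) * self.k_A + lam * self.k_B

    def b0(self, lam: float) -> float:
        return (1.0 - lam) * self.b0_A + lam * self.b0_B


class ToySystem:
    """A λ-parameterized harmonic system the Metropolis sampler can drive.

    Two flavours: a set of independent 1-D oscillators (exact analytic ΔG)
    or a 3-D bead system driven by a :class:`PerturbedTopology` plus
    per-bead harmonic tethers (needed to remove the free global translation
    of pure pair restraints).
    """

    def __init__(
        self,
        oscillators: Sequence[Oscillator1D] | None = None,
        topology: PerturbedTopology | None = None,
        tether_centers: np.ndarray | None = None,
        tether_k: float = 0.0,
        temperature: float = DEFAULT_TEMPERATURE,
    ):
        if (oscillators is None) == (topology is None):
            raise ParameterError("provide exactly one of oscillators or topology")
        self.oscillators = list(oscillators) if oscillators is not None else None
        self.topology = topology
        self.temperature = temperature
        self.tether_centers = (
            np.asarray(tether_centers, dtype=float) if tether_centers is not None else None
        )
        if topology is not None:
            if self.tether_centers is None:
                raise UnboundedSystemError(
                    "3-D pair-restraint systems need tether centers: global "
                    "translation is otherwise a flat direction"
                )
            self.n_beads = len(self.tether_centers)
            # scalar tether_k applies to every bead; an array allows leaving
            # pair-restrained beads untethered
            self.tether_k = np.broadcast_to(
                np.asarray(tether_k, dtype=float), (self.n_beads,)
            ).copy()
            if not (self.tether_k > 0).any():
                raise UnboundedSystemError("at least one bead must carry a tether")
        else:
            self.tether_k = None
            self.n_beads = len(self.oscillators)

    # -- energies -----------------------------------------------------------

    def check_bounded(self, lam: float) -> None:
        if self.oscillators is not None:
            for idx, osc in enumerate(self.oscillators):
                if osc.k(lam) <= 0:
                    raise UnboundedSystemError(
                        f"oscillator {idx} has k(λ={lam}) <= 0; the chain would diverge"
                    )
            return
        # untethered beads must sit in at least one positive-k pair term
        restrained = set(np.nonzero(self.tether_k > 0)[0] + 1)
        for p in self.topology.perturbed:
            if p.k(lam) > 0:
                restrained.update((p.i, p.j))
        for term in self.topology.static.bonded:
            if term.section_tag in ("bonds", "rubber_band") and term.params[-1] > 0:
                restrained.update(term.atom_indices)
        missing = set(range(1, self.n_beads + 1)) - restrained
        if missing:
            raise UnboundedSystemError(
                f"beads {sorted(missing)} have neither a tether nor a positive-k "
                f"restraint at λ={lam}"
            )

    def energy(self, x: np.ndarray, lam: float) -> float:
        if self.oscillators is not None:
            e = 0.0
            for xi, osc in zip(x, self.oscillators):
                e += 0.5 * osc.k(lam) * (xi - osc.b0(lam)) ** 2
            return e
        e = restraint_energy(self.topology, x, lam)
        d = x - self.tether_centers
        return e + 0.5 * float((self.tether_k * (d * d).sum(axis=1)).sum())

    def dhdl(self, x: np.ndarray, lam: float) -> float:
        if self.oscillators is not None:
            total = 0.0
            for xi, osc in zip(x, self.oscillators):
                disp = xi - osc.b0(lam)
                total += 0.5 * (osc.k_B - osc.k_A) * disp**2 - osc.k(lam) * disp * (
                    osc.b0_B - osc.b0_A
                )
            return total
        return restraint_dhdl(self.topology, x, lam)

    def initial_coords(self, lam: float) -> np.ndarray:
        if self.oscillators is not None:
            return np.array([osc.b0(lam) for osc in self.oscillators])
        return self.tether_centers.copy()


@dataclass
class WindowSamples:
    """Output of :func:`sample_window` at one λ point."""

    lam: float
    neighbor_lams: tuple[float, ...]
    times: np.ndarray  # ps
    works: dict[float, np.ndarray]  # λ' -> ΔU = U(λ') − U(λ) per sample
    dhdl: np.ndarray
    acceptance_rate: float
    step_size: float


def _tune_step(rate: float, step: float) -> float:
    if rate > 0.6:
        return step * 1.25
    if rate < 0.3:
        return step * 0.8
    return step


def sample_window(
    sys: ToySystem,
    lam: float,
    cfg: SamplerConfig,
    neighbor_lams: Sequence[float] = (),
) -> WindowSamples:
    """Equilibrium Metropolis sampling at one λ, recording neighbour ΔU.

    After ``burn_in`` sweeps (during which the proposal width is tuned
    toward a 30-60% acceptance rate and then frozen), every ``stride``-th
    sweep records ΔU = U(λ') − U(λ) for each neighbour λ' and ∂H/∂λ at λ.
    Fully deterministic for a fixed seed.
    """
    sys.check_bounded(lam)
    for nl in neighbor_lams:
        if not 0.0 <= nl <= 1.0:
            raise ParameterError(f"neighbor λ {nl} outside [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    beta = 1.0 / kt(sys.temperature)
    neighbor_lams = tuple(neighbor_lams)

    if sys.oscillators is not None:
        out = _sample_oscillators(sys, lam, cfg, neighbor_lams, rng, beta)
    else:
        out = _sample_beads3d(sys, lam, cfg, neighbor_lams, rng, beta)
    return out


def _sample_oscillators(sys, lam, cfg, neighbor_lams, rng, beta) -> WindowSamples:
    oscs = sys.oscillators
    n = len(oscs)
    k = np.array([o.k(lam) for o in oscs])
    b0 = np.array([o.b0(lam) for o in oscs])
    x = sys.initial_coords(lam)
    # per-oscillator width ~ thermal sd, times a tunable global factor
    base = np.sqrt(1.0 / (beta * k))
    factor = (cfg.step_size / base.mean()) if cfg.step_size else 1.0

    nb_k = {nl: np.array([o.k(nl) for o in oscs]) for nl in neighbor_lams}
    nb_b0 = {nl: np.array([o.b0(nl) for o in oscs]) for nl in neighbor_lams}

    works = {nl: [] for nl in neighbor_lams}
    dhdl_samples: list[float] = []
    accepted = 0
    proposed = 0
    tune_acc = 0
    tune_prop = 0
    for sweep in range(cfg.n_steps):
        trial = x + factor * base * rng.standard_normal(n)
        du = 0.5 * k * ((trial - b0) ** 2 - (x - b0) ** 2)
        accept = rng.random(n) < np.exp(np.minimum(-beta * du, 0.0))
        x = np.where(accept, trial, x)
        in_burn = sweep < cfg.burn_in
        if in_burn:
            tune_acc += int(accept.sum())
            tune_prop += n
            if cfg.step_size is None and tune_prop >= 50 * n:
                factor = _tune_step(tune_acc / tune_prop, factor)
                tune_acc = tune_prop = 0
        else:
            accepted += int(accept.sum())
            proposed += n
            prod_step = sweep - cfg.burn_in
            if prod_step % cfg.stride == 0:
                disp = x - b0
                u_here = 0.5 * k * disp**2
                for nl in neighbor_lams:
                    u_there = 0.5 * nb_k[nl] * (x - nb_b0[nl]) ** 2
                    works[nl].append(float((u_there - u_here).sum()))
                dhdl_samples.append(sys.dhdl(x, lam))
    n_samples = len(dhdl_samples)
    return WindowSamples(
        lam=lam,
        neighbor_lams=neighbor_lams,
        times=np.arange(n_samples) * SAMPLE_SPACING_PS,
        works={nl: np.asarray(v) for nl, v in works.items()},
        dhdl=np.asarray(dhdl_samples),
        acceptance_rate=accepted / proposed if proposed else 0.0,
        step_size=float(factor * base.mean()),
    )


def _sample_beads3d(sys, lam, cfg, neighbor_lams, rng, beta) -> WindowSamples:
    pos = sys.initial_coords(lam)
    n = sys.n_beads
    step = cfg.step_size or math.sqrt(1.0 / (beta * max(float(sys.tether_k.max()), 1.0)))

    works = {nl: [] for nl in neighbor_lams}
    dhdl_samples: list[float] = []
    accepted = 0
    proposed = 0
    tune_acc = 0
    tune_prop = 0
    u_cur = sys.energy(pos, lam)
    for sweep in range(cfg.n_steps):
        for b in range(n):
            old = pos[b].copy()
            pos[b] = old + step * rng.standard_normal(3)
            u_new = sys.energy(pos, lam)
            if rng.random() < math.exp(min(-beta * (u_new - u_cur), 0.0)):
                u_cur = u_new
                if sweep >= cfg.burn_in:
                    accepted += 1
                else:
                    tune_acc += 1
            else:
                pos[b] = old
            if sweep >= cfg.burn_in:
                proposed += 1
            else:
                tune_prop += 1
        if sweep < cfg.burn_in and cfg.step_size is None and tune_prop >= 50 * n:
            step = _tune_step(tune_acc / tune_prop, step)
            tune_acc = tune_prop = 0
        if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.stride == 0:
            for nl in neighbor_lams:
                works[nl].append(sys.energy(pos, nl) - u_cur)
            dhdl_samples.append(sys.dhdl(pos, lam))
    n_samples = len(dhdl_samples)
    return WindowSamples(
        lam=lam,
        neighbor_lams=neighbor_lams,
        times=np.arange(n_samples) * SAMPLE_SPACING_PS,
        works={nl: np.asarray(v) for nl, v in works.items()},
        dhdl=np.asarray(dhdl_samples),
        acceptance_rate=accepted / proposed if proposed else 0.0,
        step_size=float(step),
    )


def sample_schedule(
    sys: ToySystem,
    schedule: LambdaSchedule,
    cfg: SamplerConfig,
) -> list[WindowSamples]:
    """Sample every schedule point with neighbour ΔU recording.

    Each window gets an independent chain seeded from ``cfg.seed`` and the
    window index, so runs are reproducible and windows uncorrelated.
    """
    results = []
    vals = list(schedule)
    for idx, lam in enumerate(vals):
        neighbors = []
        if idx > 0:
            neighbors.append(vals[idx - 1])
        if idx < len(vals) - 1:
            neighbors.append(vals[idx + 1])
        wcfg = SamplerConfig(
            n_steps=cfg.n_steps,
            burn_in=cfg.burn_in,
            stride=cfg.stride,
            step_size=cfg.step_size,
            seed=cfg.seed * 100003 + idx,
        )
        results.append(sample_window(sys, lam, wcfg, neighbors))
    return results


def windows_from_samples(
    samples: Sequence[WindowSamples],
    schedule: LambdaSchedule,
    temperature: float,
) -> list[WindowWorkData]:
    """Pair adjacent per-λ samples into interval work data."""
    vals = list(schedule)
    out = []
    for idx in range(len(vals) - 1):
        lo, hi = vals[idx], vals[idx + 1]
        out.append(
            WindowWorkData(
                lambda_low=lo,
                lambda_high=hi,
                forward_time=samples[idx].times,
                forward_work=samples[idx].works[hi],
                reverse_time=samples[idx + 1].times,
                reverse_work=samples[idx + 1].works[lo],
                temperature=temperature,
            )
        )
    return out


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def analytic_dG(sys: ToySystem) -> float:
    """Exact ΔG (λ 0→1) for independent 1-D oscillators, kJ/mol.

    ΔG = (k_B·T/2)·Σ ln(k_B,i / k_A,i); shifts of b0 contribute nothing.
    """
    if sys.oscillators is None:
        raise UnsupportedSystemError(
            "closed form is valid for independent 1-D oscillators only; "
            "use the sampler-based estimate for coupled 3-D systems"
        )
    total = 0.0
    for idx, osc in enumerate(sys.oscillators):
        if osc.k_A <= 0 or osc.k_B <= 0:
            raise UnsupportedSystemError(
                f"oscillator {idx} has a zero-k endpoint; its endpoint partition "
                f"function is divergent"
            )
        total += math.log(osc.k_B / osc.k_A)
    return 0.5 * kt(sys.temperature) * total


def gaussian_work_pair(
    mu: float,
    sigma: float,
    n: int,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
    lambda_low: float = 0.0,
    lambda_high: float = 1.0,
) -> WindowWorkData:
    """Crooks-consistent synthetic work data with known ΔG.

    Forward work ~ N(μ, σ²), reverse ~ N(−μ + βσ², σ²); the implied true
    free-energy difference μ − βσ²/2 is stored on the result as ``true_dG``.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if n < 1:
        raise ParameterError("n must be >= 1")
    beta = 1.0 / kt(temperature)
    rng = np.random.default_rng(seed)
    fwd = mu + sigma * rng.standard_normal(n)
    rev = (-mu + beta * sigma**2) + sigma * rng.standard_normal(n)
    times = np.arange(n) * SAMPLE_SPACING_PS
    return WindowWorkData(
        lambda_low=lambda_low,
        lambda_high=lambda_high,
        forward_time=times,
        forward_work=fwd,
        reverse_time=times.copy(),
        reverse_work=rev,
        temperature=temperature,
        true_dG=mu - beta * sigma**2 / 2.0,
    )


# ---------------------------------------------------------------------------
# fixture structures and topologies
# ---------------------------------------------------------------------------

_SC_COUNTS = (1, 0, 1, 1, 0, 2, 1, 0, 1, 1)  # repeating side-chain pattern
_RES_NAMES = ("ALA", "GLY", "LEU", "LYS", "GLY", "PHE", "SER", "GLY", "VAL", "GLU")


def _chain_beads(bb_positions: np.ndarray, n_residues: int, rng) -> list[Bead]:
    beads = []
    idx = 1
    for r in range(n_residues):
        resname = _RES_NAMES[r % len(_RES_NAMES)]
        beads.append(Bead(idx, "BB", r + 1, resname, tuple(bb_positions[r])))
        idx += 1
        for s in range(_SC_COUNTS[r % len(_SC_COUNTS)]):
            offset = 0.3 * _unit(rng.standard_normal(3))
            beads.append(
                Bead(idx, f"SC{s + 1}", r + 1, resname, tuple(bb_positions[r] + offset))
            )
            idx += 1
    return beads


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def _helix_backbone(n: int) -> np.ndarray:
    # compact helical arc: ~0.35 nm consecutive BB spacing, pitch chosen so
    # that i/i+3..i+4 contacts fall inside the 0.9 nm cutoff
    radius, rise, turn = 0.23, 0.15, math.radians(100.0)
    t = np.arange(n)
    return np.column_stack(
        [radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t]
    )


def _extended_backbone(n: int) -> np.ndarray:
    return np.column_stack([0.35 * np.arange(n), np.zeros(n), np.zeros(n)])


def _random_backbone(n: int, rng) -> np.ndarray:
    steps = 0.35 * np.array([_unit(rng.standard_normal(3)) for _ in range(n - 1)])
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def make_fixture_structures(
    n_residues: int, mode: str = "helix_like", seed: int = 0
) -> tuple[BeadStructure, BeadStructure]:
    """Deterministic (state A, state B) structure pair.

    The two structures share an identical atom composition (names, residues)
    but different geometries. ``helix_like``: compact helix vs extended
    chain; ``extended``: two noisy extended chains; ``random``: two
    independent self-avoiding-ish random walks.
    """
    if n_residues < 3:
        raise ParameterError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if mode == "helix_like":
        bb_a = _helix_backbone(n_residues)
        bb_b = _extended_backbone(n_residues)
    elif mode == "extended":
        bb_a = _extended_backbone(n_residues) + 0.02 * rng.standard_normal((n_residues, 3))
        bb_b = _extended_backbone(n_residues) + 0.02 * rng.standard_normal((n_residues, 3))
    elif mode == "random":
        bb_a = _random_backbone(n_residues, rng)
        bb_b = _random_backbone(n_residues, rng)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    # side-chain offsets must be identical in count, so reuse one rng stream
    # per structure but the same residue pattern
    beads_a = _chain_beads(bb_a, n_residues, np.random.default_rng(seed + 1))
    beads_b = _chain_beads(bb_b, n_residues, np.random.default_rng(seed + 2))
    return (
        BeadStructure(beads_a, title=f"fixture {mode} A"),
        BeadStructure(beads_b, title=f"fixture {mode} B"),
    )


def fixture_topology(
    structure: BeadStructure,
    network,
    molecule_name: str = "toy",
    bond_b0: float = 0.35,
    bond_k: float = 1250.0,
) -> Topology:
    """Build a minimal Martini-style topology for a fixture structure.

    Consecutive-backbone bonds get fixed shared parameters (identical in
    every state, hence static under mixing); the elastic network supplies
    the state-specific rubber bands.
    """
    atoms = [
        AtomRecord(
            index=b.index,
            type="P1" if b.name == "BB" else "C1",
            residue_index=b.residue_index,
            residue_name=b.residue_name,
            bead_name=b.name,
            charge=0.0,
        )
        for b in structure.beads
    ]
    bonded: list[BondedTerm] = []
    backbone = [b for b in structure.beads if b.name == "BB"]
    for a, b in zip(backbone, backbone[1:]):
        bonded.append(BondedTerm((a.index, b.index), 1, (bond_b0, bond_k), "bonds"))
    for t in network.terms:
        bonded.append(BondedTerm((t.i, t.j), 6, (round(t.b0, 5), t.k), "rubber_band"))
    top = Topology(molecule_name=molecule_name, nrexcl=1, atoms=atoms, bonded=bonded)
    top.validate()
    return top


def build_toy_from_fixture(
    n_residues: int,
    mode: str = "helix_like",
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    tether_k: float = 100.0,
    cutoff: float = 0.9,
    network_k: float = 500.0,
) -> ToySystem:
    """Fixture structures → networks → mixed topology → sampleable system.

    Every bead is tethered (k ``tether_k``) to its state-A position so the
    pair-restraint system is bounded at all λ.
    """
    from .cg_structures import select_backbone
    from .elastic_network import build_network
    from .perturbation import mix_topologies

    struct_a, struct_b = make_fixture_structures(n_residues, mode=mode, seed=seed)
    bb_a = select_backbone(struct_a)
    bb_b = select_backbone(struct_b)
    net_a = build_network(bb_a, cutoff=cutoff, k=network_k, source_label="A")
    net_b = build_network(bb_b, cutoff=cutoff, k=network_k, source_label="B")
    top_a = fixture_topology(struct_a, net_a, molecule_name="toy")
    top_b = fixture_topology(struct_b, net_b, molecule_name="toy")
    pt = mix_topologies(top_a, top_b)
    return ToySystem(
        topology=pt,
        tether_centers=struct_a.positions,
        tether_k=tether_k,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# window-file output (same dialect free_energy.read_work_data consumes)
# ---------------------------------------------------------------------------

def write_window_files(
    samples: Sequence[WindowSamples],
    schedule: LambdaSchedule,
    out_dir,
    fmt: str = "xvg",
) -> list[Path]:
    """Write one per-λ table per schedule point; returns the paths.

    Columns: time, then ΔU to each neighbour λ ascending. ``fmt`` picks the
    comment dialect only ("xvg" → '@' headers, "tsv" → '#').
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("xvg", "tsv"):
        raise ParameterError(f"unknown format {fmt!r}")
    paths = []
    for idx, smp in enumerate(samples):
        suffix = "xvg" if fmt == "xvg" else "tsv"
        path = out_dir / f"window_{idx:03d}.{suffix}"
        neighbors = sorted(smp.neighbor_lams)
        with open(path, "w") as fh:
            if fmt == "xvg":
                fh.write(f"@    title \"dU samples at lambda = {smp.lam}\"\n")
                fh.write("@    xaxis  label \"Time (ps)\"\n")
                for col, nl in enumerate(neighbors):
                    fh.write(f"@ s{col} legend \"dU to lambda = {nl}\"\n")
            else:
                fh.write(f"# dU samples at lambda = {smp.lam}\n")
                fh.write(f"# columns: time_ps {' '.join(f'dU_to_{nl}' for nl in neighbors)}\n")
            for row in range(len(smp.times)):
                cols = [f"{smp.times[row]:.1f}"]
                cols += [f"{smp.works[nl][row]:.10g}" for nl in neighbors]
                fh.write("\t".join(cols) + "\n")
        paths.append(path)
    return paths


def write_dhdl_files(
    samples: Sequence[WindowSamples], out_dir, fmt: str = "tsv"
) -> list[Path]:
    """Write per-λ ∂H/∂λ series (time, dH/dλ) next to the window files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, smp in enumerate(samples):
        path = out_dir / f"dhdl_{idx:03d}.{fmt}"
        with open(path, "w") as fh:
            fh.write(f"# dH/dlambda at lambda = {smp.lam}\n")
            for t, v in zip(smp.times, smp.dhdl):
                fh.write(f"{t:.1f}\t{v:.10g}\n")
        paths.append(path)
    return paths
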