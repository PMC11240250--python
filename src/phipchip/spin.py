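"""Density-matrix simulation of singlet-to-13C polarization transfer.

The hydrogenation adds the two parahydrogen protons to the product as a
nuclear singlet pair.  In the 13C-labelled product the heteronuclear
J couplings break the magnetic equivalence of the pair, which an echo-train
sequence exploits to convert the NMR-silent singlet population into
observable 13C magnetization.  This module provides the spin-system
container, exact unitary propagation under the rotating-frame J-coupling
Hamiltonian, ideal hard pulses, singlet-triplet mixing under a hydride
chemical-shift difference, the purge + echo-train transfer sequence, and a
grid optimizer over its parameters.

Conventions: spins are ordered as listed in the :class:`SpinSystem` (the
bundled fixture uses (Ha, Hb, C)); the basis is the Zeeman product basis;
each isotope lives in its own rotating frame, so heteronuclear J couplings
are truncated to their secular ``2 pi J Iz Sz`` part while homonuclear
couplings keep the full scalar form.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence
import tomllib

import numpy as np

_SUPPORTED_ISOTOPES = ("1H", "13C")

_SX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_SY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_SZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_E2 = np.eye(2, dtype=complex)


class UnsupportedSystemError(ValueError):
    """The requested operation does not support this spin topology."""


@dataclass(frozen=True)
class SpinSystem:
    """An isotope list with offsets (Hz) and a symmetric J-coupling matrix (Hz)."""

    isotopes: tuple[str, ...]
    offsets_hz: tuple[float, ...]
    j_couplings_hz: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.isotopes)
        for iso in self.isotopes:
            if iso not in _SUPPORTED_ISOTOPES:
                raise UnsupportedSystemError(f"unsupported isotope {iso!r}")
        if len(self.offsets_hz) != n:
            raise ValueError("offsets length must match isotope count")
        j = np.asarray(self.j_couplings_hz, dtype=float)
        if j.shape != (n, n):
            raise ValueError("J matrix shape must match isotope count")
        if not np.allclose(j, j.T):
            raise ValueError("J matrix must be symmetric")
        if np.any(np.diag(j) != 0):
            raise ValueError("J matrix diagonal must be zero")
        object.__setattr__(
            self, "j_couplings_hz", tuple(tuple(float(v) for v in row) for row in j)
        )

    @property
    def n_spins(self) -> int:
        return len(self.isotopes)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    @property
    def j_matrix(self) -> np.ndarray:
        return np.asarray(self.j_couplings_hz, dtype=float)

    def spins_of(self, isotope: str) -> tuple[int, ...]:
        return tuple(i for i, iso in enumerate(self.isotopes) if iso == isotope)


def fumarate_13c1() -> SpinSystem:
    """Three-spin system of the singly 13C-labelled trans-dicarboxylate.

    The two vinylic protons are chemically equivalent (offsets 0 in the
    rotating frame); the carboxylate 13C breaks the symmetry through its
    unequal two- and three-bond couplings to the pair.  J values are
    transcribed from the published coupling network of the labelled compound
    (proton-proton ~15.9 Hz; carbon-proton couplings of a few Hz differing by
    ~3.6 Hz between the two protons).
    """
    return SpinSystem(
        isotopes=("1H", "1H", "13C"),
        offsets_hz=(0.0, 0.0, 0.0),
        j_couplings_hz=(
            (0.0, 15.9, 3.2),
            (15.9, 0.0, 6.8),
            (3.2, 6.8, 0.0),
        ),
    )


def load_spin_system(path) -> SpinSystem:
    """Read a spin system from TOML (keys: isotopes, offsets_hz, j_couplings_hz)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return SpinSystem(
        isotopes=tuple(data["isotopes"]),
        offsets_hz=tuple(float(v) for v in data.get("offsets_hz", [0.0] * len(data["isotopes"]))),
        j_couplings_hz=tuple(tuple(float(v) for v in row) for row in data["j_couplings_hz"]),
    )


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _single_spin_ops(n: int) -> tuple[tuple[np.ndarray, ...], ...]:
    """(Ix, Iy, Iz) product operators for each of n spins, cached by size."""
    out = []
    for axis_op in (_SX, _SY, _SZ):
        ops = []
        for i in range(n):
            m = np.array([[1.0 + 0j]])
            for k in range(n):
                m = np.kron(m, axis_op if k == i else _E2)
            ops.append(m)
        out.append(tuple(ops))
    return tuple(out)


def spin_operators(system: SpinSystem):
    """Return (Ix, Iy, Iz) lists of product operators for the system."""
    return _single_spin_ops(system.n_spins)


def hamiltonian(system: SpinSystem) -> np.ndarray:
    """Rotating-frame Hamiltonian in rad/s.

    Offsets enter as ``2 pi nu Iz``; homonuclear pairs couple through the full
    scalar product ``2 pi J I.I`` (strong coupling), heteronuclear pairs
    through the secular ``2 pi J Iz Sz`` only.
    """
    ix, iy, iz = spin_operators(system)
    n = system.n_spins
    h = np.zeros((system.dim, system.dim), dtype=complex)
    for i, nu in enumerate(system.offsets_hz):
        if nu:
            h += 2 * np.pi * nu * iz[i]
    j = system.j_matrix
    for i in range(n):
        for k in range(i + 1, n):
            if j[i, k] == 0:
                continue
            if system.isotopes[i] == system.isotopes[k]:
                h += 2 * np.pi * j[i, k] * (ix[i] @ ix[k] + iy[i] @ iy[k] + iz[i] @ iz[k])
            else:
                h += 2 * np.pi * j[i, k] * (iz[i] @ iz[k])
    return h


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------


@dataclass
class DensityState:
    """Hermitian, unit-trace operator over the Zeeman product basis."""

    matrix: np.ndarray
    basis: str = "Zeeman product basis, spins in system order"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        self.validate()

    def validate(self, tol: float = 1e-10) -> None:
        if abs(np.trace(self.matrix) - 1.0) > tol:
            raise ValueError(f"trace {np.trace(self.matrix)} != 1")
        if np.max(np.abs(self.matrix - self.matrix.conj().T)) > tol:
            raise ValueError("matrix is not Hermitian")
        eigs = np.linalg.eigvalsh(self.matrix)
        if eigs.min() < -1e-9:
            raise ValueError(f"negative eigenvalue {eigs.min()}")

    def expectation(self, operator: np.ndarray) -> float:
        return float(np.real(np.trace(self.matrix @ operator)))

    def copy(self) -> "DensityState":
        return DensityState(self.matrix.copy(), self.basis)


def _singlet_ket() -> np.ndarray:
    up = np.array([1.0, 0.0], dtype=complex)
    dn = np.array([0.0, 1.0], dtype=complex)
    return (np.kron(up, dn) - np.kron(dn, up)) / np.sqrt(2.0)


def singlet_state(system: SpinSystem, pair: tuple[int, int] = (0, 1)) -> DensityState:
    """|S0><S0| on the proton pair, maximally mixed on every other spin."""
    i, k = pair
    if system.isotopes[i] != "1H" or system.isotopes[k] != "1H":
        raise TypeError("singlet pair must be two 1H spins")
    if i == k:
        raise ValueError("pair indices must differ")
    ket = _singlet_ket()
    pair_proj = np.outer(ket, ket.conj())
    # build the full-space projector by permuting the pair to the front
    rest = [s for s in range(system.n_spins) if s not in (i, k)]
    order = [i, k] + rest
    rho_front = pair_proj
    for _ in rest:
        rho_front = np.kron(rho_front, _E2 / 2.0)
    perm = _permutation(order, system.n_spins)
    rho = perm @ rho_front @ perm.T
    return DensityState(rho)


def _permutation(order: Sequence[int], n: int) -> np.ndarray:
    """Matrix mapping the basis ordered by ``order`` back to natural order."""
    dim = 2 ** n
    p = np.zeros((dim, dim))
    for idx in range(dim):
        bits = [(idx >> (n - 1 - s)) & 1 for s in range(n)]  # natural-order bits
        src_bits = [bits[s] for s in order]
        src = 0
        for b in src_bits:
            src = (src << 1) | b
        p[idx, src] = 1.0
    return p


def singlet_projector(system: SpinSystem, pair: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Projector onto the singlet of the pair (identity on the other spins)."""
    ix, iy, iz = spin_operators(system)
    i, k = pair
    dot = ix[i] @ ix[k] + iy[i] @ iy[k] + iz[i] @ iz[k]
    return 0.25 * np.eye(system.dim) - dot


def triplet0_projector(system: SpinSystem, pair: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Projector onto the central triplet |T0> of the pair."""
    ix, iy, iz = spin_operators(system)
    i, k = pair
    # |T0><T0| = 1/4 + IxIx + IyIy - IzIz
    return (
        0.25 * np.eye(system.dim)
        + ix[i] @ ix[k]
        + iy[i] @ iy[k]
        - iz[i] @ iz[k]
    )


# ---------------------------------------------------------------------------
# Propagation primitives
# ---------------------------------------------------------------------------


def _propagator(h: np.ndarray, duration_s: float) -> np.ndarray:
    energies, vectors = np.linalg.eigh(h)
    phases = np.exp(-1j * energies * duration_s)
    return (vectors * phases) @ vectors.conj().T


def _apply(state: DensityState, u: np.ndarray) -> DensityState:
    return DensityState(u @ state.matrix @ u.conj().T, state.basis)


def evolve(state: DensityState, system: SpinSystem, duration_s: float) -> DensityState:
    """Free evolution by exact exponentiation of the coupling Hamiltonian."""
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if duration_s == 0:
        return state.copy()
    return _apply(state, _propagator(hamiltonian(system), duration_s))


def pulse(
    state: DensityState,
    system: SpinSystem,
    channel: str,
    angle_rad: float,
    phase_rad: float = 0.0,
) -> DensityState:
    """Ideal (zero-duration) hard pulse on every spin of one isotope channel."""
    spins = system.spins_of(channel)
    if not spins:
        raise UnsupportedSystemError(f"no {channel!r} spins in system")
    ix, iy, _ = spin_operators(system)
    gen = sum(
        np.cos(phase_rad) * ix[i] + np.sin(phase_rad) * iy[i] for i in spins
    )
    return _apply(state, _propagator(gen, angle_rad))


def st_mixing(
    state: DensityState,
    system: SpinSystem,
    delta_hydride_hz: float,
    duration_s: float,
    pair: tuple[int, int] = (0, 1),
) -> DensityState:
    """Coherent singlet-triplet mixing of the proton pair in a hydride intermediate.

    While the pair resides on the catalyst metal centre the two protons see a
    chemical-shift difference ``delta_hydride_hz``, whose Hamiltonian
    ``pi * delta * (I1z - I2z)`` interconverts |S0> and |T0>.  For an isolated
    pair with no J coupling the singlet population follows the two-level Rabi
    formula, with complete S0 -> T0 transfer at ``t = 1/(2 delta)``.  The
    outer triplet states |T+->, being diagonal in (I1z - I2z), are untouched.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if duration_s == 0 or delta_hydride_hz == 0:
        return state.copy()
    _, _, iz = spin_operators(system)
    i, k = pair
    h = np.pi * delta_hydride_hz * (iz[i] - iz[k])
    return _apply(state, _propagator(h, duration_s))


# ---------------------------------------------------------------------------
# Purge + echo-train transfer sequence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceParams:
    """Echo delay tau (s), echo counts of the two trains, and the purge flag."""

    tau_s: float
    n1: int = 7
    n2: int = 7
    purge: bool = True

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau must be > 0")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")

    @property
    def total_duration_s(self) -> float:
        # each echo is tau - pi - tau, plus the junction delay tau
        return (2 * self.n1 + 2 * self.n2 + 1) * self.tau_s


@dataclass(frozen=True)
class RelaxationParams:
    """Phenomenological lifetimes: proton singlet order T_S and 13C T1 (s)."""

    t_singlet_s: float
    t1_carbon_s: float

    def __post_init__(self) -> None:
        if self.t_singlet_s <= 0 or self.t1_carbon_s <= 0:
            raise ValueError("lifetimes must be > 0")


def _relaxed_delay(
    state: DensityState,
    system: SpinSystem,
    duration_s: float,
    relaxation: Optional[RelaxationParams],
    pair: tuple[int, int],
    carbon: int,
) -> DensityState:
    """Free evolution with phenomenological exponential relaxation.

    Not a Lindblad treatment: during every delay the carbon Zeeman order
    (the already-transferred magnetization) decays with T1, and every other
    deviation from equilibrium - the stored singlet order and the
    proton-coherence intermediates the echo train works through - decays with
    the singlet lifetime T_S.  This reproduces the two lifetimes the
    experiment reasons in terms of, and gives the correct limits (T_S -> 0
    destroys the transfer; T_S -> inf recovers the unitary result).
    """
    out = evolve(state, system, duration_s)
    if relaxation is None or duration_s == 0:
        return out
    _, _, iz = spin_operators(system)
    dim = system.dim
    f_s = np.exp(-duration_s / relaxation.t_singlet_s)
    f_1 = np.exp(-duration_s / relaxation.t1_carbon_s)
    izc = iz[carbon]
    cz = np.real(np.trace(out.matrix @ izc)) / np.real(np.trace(izc @ izc))
    deviation = out.matrix - np.eye(dim) / dim - cz * izc
    rho = np.eye(dim) / dim + f_s * deviation + f_1 * cz * izc
    return DensityState(rho, state.basis)


def _transfer_topology(system: SpinSystem) -> tuple[tuple[int, int], int]:
    protons = system.spins_of("1H")
    carbons = system.spins_of("13C")
    if len(protons) < 2 or len(carbons) != 1:
        raise UnsupportedSystemError(
            "transfer sequence supports >=2 protons and exactly one 13C; "
            f"got {system.isotopes}"
        )
    return (protons[0], protons[1]), carbons[0]


def s2hm(
    state: DensityState,
    system: SpinSystem,
    params: SequenceParams,
    relaxation: Optional[RelaxationParams] = None,
) -> DensityState:
    """Purge + singlet-to-heteronuclear-magnetization echo-train sequence.

    Layout (all pulses ideal; pi pulses on the 13C channel, phase x):

        [90x(1H) purge]  -  (tau - 180x - tau) x n1  -  tau - 90x(13C)
                         -  (tau - 180x - tau) x n2  -  90y(13C)

    The echo spacing 2*tau is matched to the proton singlet-triplet splitting
    (tau ~ 1/(4 J_HH)); the pi pulses toggle the sign of the heteronuclear
    coupling-difference term, which resonantly drives |S0> -> |T0> coherence
    correlated with the 13C state.  The first train builds that coherence, the
    junction 90 converts it to a transverse-carbon form (the extra tau keeps
    the junction pulse one full echo period after the last refocusing pulse),
    the second train rephases it into net carbon magnetization, and the final
    90, phase-shifted by 90 degrees, stores it along +z.  An optional pi/2
    proton purge pulse first empties the |T0> state into |T+-> so that
    catalyst-induced singlet-triplet leakage cannot cancel the transferred
    signal.
    """
    pair, carbon = _transfer_topology(system)
    out = state
    if params.purge:
        out = pulse(out, system, "1H", np.pi / 2, 0.0)

    def delay(s: DensityState) -> DensityState:
        return _relaxed_delay(s, system, params.tau_s, relaxation, pair, carbon)

    for _ in range(params.n1):
        out = delay(out)
        out = pulse(out, system, "13C", np.pi, 0.0)
        out = delay(out)
    out = delay(out)
    out = pulse(out, system, "13C", np.pi / 2, 0.0)
    for _ in range(params.n2):
        out = delay(out)
        out = pulse(out, system, "13C", np.pi, 0.0)
        out = delay(out)
    out = pulse(out, system, "13C", np.pi / 2, np.pi / 2)
    return out


def transfer_efficiency(
    system: SpinSystem,
    params: SequenceParams,
    relaxation: Optional[RelaxationParams] = None,
) -> float:
    """Fraction of the proton singlet order converted to 13C z-magnetization.

    Runs the sequence from a pure proton singlet (carbon unpolarized) and
    returns ``2 <Iz(13C)>``, normalized so 1 means complete conversion of the
    singlet order into carbon polarization.
    """
    pair, carbon = _transfer_topology(system)
    state = singlet_state(system, pair)
    final = s2hm(state, system, params, relaxation)
    _, _, iz = spin_operators(system)
    return 2.0 * final.expectation(iz[carbon])


def unitary_transfer_bound(system: SpinSystem) -> float:
    """Best 2<Iz(13C)> any unitary could reach from the singlet initial state.

    From the eigenvalue majorization argument: sort the eigenvalues of the
    initial state against those of the target operator.
    """
    pair, carbon = _transfer_topology(system)
    rho = singlet_state(system, pair).matrix
    _, _, iz = spin_operators(system)
    p = np.sort(np.linalg.eigvalsh(rho))[::-1]
    q = np.sort(np.linalg.eigvalsh(iz[carbon]))[::-1]
    return 2.0 * float(p @ q)


def optimize_sequence(
    system: SpinSystem,
    tau_grid_s: Sequence[float],
    n_grid: Sequence[tuple[int, int]] = ((7, 7),),
    relaxation: Optional[RelaxationParams] = None,
    purge: bool = True,
):
    """Exhaustive grid search of the transfer efficiency.

    Returns ``(best_params, records)`` where records is a list of
    ``(tau_s, n1, n2, efficiency)`` tuples for every grid point.  Ties are
    broken deterministically toward the smallest tau, then the smallest
    n1 + n2.
    """
    taus = [float(t) for t in tau_grid_s]
    pairs = [(int(a), int(b)) for a, b in n_grid]
    if not taus or not pairs:
        raise ValueError("grids must be non-empty")
    records = []
    for n1, n2 in pairs:
        for tau in taus:
            eff = transfer_efficiency(
                system, SequenceParams(tau, n1, n2, purge), relaxation
            )
            records.append((tau, n1, n2, eff))
    best_eff = max(r[3] for r in records)
    tau, n1, n2, _ = min(
        (r for r in records if r[3] == best_eff),
        key=lambda r: (r[0], r[1] + r[2]),
    )
    return SequenceParams(tau, n1, n2, purge), records
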