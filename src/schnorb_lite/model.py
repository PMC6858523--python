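"""The Hamiltonian-prediction network.

Three stages, mirroring the message-passing architecture the package is named
after:

1. *Atomic environments*: element embeddings refined by T continuous-filter
   convolution (cfconv) interaction blocks; rotation- and translation-invariant
   per-atom feature vectors of width B.
2. *Pair environments*: 2L+1 pair-interaction blocks (one per angular-momentum
   order lambda = 0 .. 2L) build invariant pair coefficients p_ij^lambda from a
   factorized tensor product of the two atom representations and a radial
   filter, plus environment sums over third atoms.  Each order is projected
   onto D learned directions along the unit bond vector (covariant for
   lambda > 0), and elementwise products over orders yield features
   Omega_ij^l carrying angular momentum up to 2L.
3. *Heads*: purely linear maps from Omega features to off-site and on-site
   blocks of H (and S), cropped to each atom's orbital count and symmetrized;
   a per-element constant on-site overlap block; and an atom-wise MLP energy
   head whose negative position-gradient provides forces.

Everything is built from :mod:`schnorb_lite.autodiff` tensors, so energies,
forces and every matrix entry are analytically differentiable with respect to
atomic positions and parameters.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, constant, tensor
from .chem import BasisSet, ConfigurationError, Molecule, OrbitalIndex, build_orbital_index

LN2 = np.log(2.0)


def ssp(x: Tensor) -> Tensor:
    """Shifted softplus ln(e^x / 2 + 1/2); zero at zero, asymptotically linear."""
    return ad.softplus(x) - LN2


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters plus the element/orbital bookkeeping."""

    elements: tuple              # sorted nuclear charges the model supports
    n_ao: dict                   # element -> orbital count
    L: int                       # maximal basis angular momentum
    basis_name: str = "custom"
    B: int = 64                  # atom feature width
    D: int = 4                   # projection directions
    T: int = 3                   # SchNet interaction blocks
    r_c: float = 5.0             # cutoff, Angstrom
    delta_mu: float = 0.25       # radial grid spacing, Angstrom
    gamma: float = 10.0          # radial width, Angstrom^-2
    n_hidden: int = 64           # hidden width of mlp blocks

    def __post_init__(self):
        self.elements = tuple(sorted(int(z) for z in self.elements))
        self.n_ao = {int(z): int(v) for z, v in self.n_ao.items()}
        if min(self.B, self.D, self.T + 1, self.n_hidden) < 1:
            raise ConfigurationError("B, D, n_hidden must be >= 1 and T >= 0")
        if not 0 <= self.L <= 3:
            raise ConfigurationError("L must be within 0..3")
        if min(self.r_c, self.delta_mu, self.gamma) <= 0:
            raise ConfigurationError("r_c, delta_mu, gamma must be positive")

    @property
    def n_ao_max(self) -> int:
        return max(self.n_ao.values())

    @property
    def n_orders(self) -> int:
        return 2 * self.L + 1        # angular-momentum orders lambda = 0 .. 2L

    @property
    def n_rbf(self) -> int:
        return int(np.floor(self.r_c / self.delta_mu)) + 1

    @classmethod
    def from_basis(cls, basis: BasisSet, **kw) -> "ModelConfig":
        elements = tuple(sorted(basis.shells))
        return cls(elements=elements,
                   n_ao={z: basis.n_ao(z) for z in elements},
                   L=basis.max_l(), basis_name=basis.name, **kw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["elements"] = list(self.elements)
        d["n_ao"] = {str(z): v for z, v in self.n_ao.items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["elements"] = tuple(d["elements"])
        d["n_ao"] = {int(z): v for z, v in d["n_ao"].items()}
        return cls(**d)


# -- parameter initialization ------------------------------------------

def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def init_params(config: ModelConfig, seed: int = 0) -> dict:
    """Seeded parameter dictionary; every value is a differentiable Tensor."""
    rng = np.random.default_rng(seed)
    P = {}

    def linear(name, n_in, n_out):
        P[f"{name}.W"] = tensor(_glorot(rng, n_in, n_out))
        P[f"{name}.b"] = tensor(np.zeros(n_out))

    def mlp(name, n_in, n_hid, n_out):
        linear(f"{name}.1", n_in, n_hid)
        linear(f"{name}.2", n_hid, n_out)

    B, H, M2 = config.B, config.n_hidden, config.n_ao_max ** 2
    zmax = max(config.elements)
    emb = np.zeros((zmax + 1, B))
    for z in config.elements:
        emb[z] = rng.standard_normal(B) / np.sqrt(B)
    P["embed"] = tensor(emb)

    for t in range(config.T):
        linear(f"schnet{t}.in", B, B)
        mlp(f"schnet{t}.filter", config.n_rbf, B, B)
        mlp(f"schnet{t}.atom", B, H, B)

    for lam in range(config.n_orders):
        linear(f"orb{lam}.fac", B, B)
        mlp(f"orb{lam}.filter", config.n_rbf, B, B)
        linear(f"orb{lam}.mix", B, B)
        mlp(f"orb{lam}.atom", B, H, B)
        mlp(f"orb{lam}.pair", B, H, B)
        mlp(f"orb{lam}.env", B, H, B)
        if lam > 0:
            P[f"orb{lam}.dir"] = tensor(_glorot(rng, 3, config.D))

    for l in range(config.n_orders):
        linear(f"head.h_off{l}", B * config.D, M2)
        linear(f"head.h_on{l}", B * config.D, M2)
        linear(f"head.s_off{l}", B * config.D, M2)

    s_on = np.zeros((zmax + 1, M2))
    eye = np.eye(config.n_ao_max).ravel()
    for z in config.elements:
        s_on[z] = eye                      # analytic self-overlap of normalized AOs
    P["head.s_on"] = tensor(s_on)

    mlp("energy", B, H, 1)
    return P


def _linear(P, name, x):
    return x @ P[f"{name}.W"] + P[f"{name}.b"]


def _mlp(P, name, x):
    return _linear(P, f"{name}.2", ssp(_linear(P, f"{name}.1", x)))


# -- forward pass -------------------------------------------------------

class Forward:
    """One differentiable forward evaluation for a single molecule.

    Exposes the graph tensors (H, S, E and the position leaf) so that callers
    can take gradients of any scalar derived from them.
    """

    def __init__(self, params: dict, config: ModelConfig, mol: Molecule,
                 index: OrbitalIndex = None, positions: np.ndarray = None):
        self.params, self.config, self.mol = params, config, mol
        for z in set(mol.atomic_numbers):
            if z not in config.elements:
                raise ConfigurationError(f"model has no embedding for element Z={z}")
        if index is None:
            index = OrbitalIndex(
                np.concatenate([[0], np.cumsum([config.n_ao[z] for z in mol.atomic_numbers])[:-1]]),
                np.array([config.n_ao[z] for z in mol.atomic_numbers]), [])
        self.index = index
        self.pos = tensor(mol.positions if positions is None else positions)
        self._run()

    # neighbor list (numpy level; the cutoff makes the filter vanish smoothly)
    def _pairs(self):
        pos = self.pos.value
        n = self.mol.n_atoms
        diff = pos[None, :, :] - pos[:, None, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        ii, jj = np.where((dist < self.config.r_c) & ~np.eye(n, dtype=bool))
        return ii.astype(np.intp), jj.astype(np.intp)

    def _filter(self, name, g, fcut):
        return _mlp(self.params, name, g) * fcut

    def _run(self):
        P, cfg, mol = self.params, self.config, self.mol
        n = mol.n_atoms
        i_idx, j_idx = self._pairs()
        self.i_idx, self.j_idx = i_idx, j_idx

        rvec = ad.take(self.pos, j_idx) - ad.take(self.pos, i_idx)
        dist = ad.sqrt(ad.tsum(rvec * rvec, axis=1))
        dcol = ad.reshape(dist, (-1, 1))
        mu = np.arange(cfg.n_rbf) * cfg.delta_mu
        g = ad.exp(constant(-cfg.gamma) * (dcol - constant(mu)) ** 2)
        inside = (dist.value < cfg.r_c).astype(float)
        fcut = ad.reshape(constant(0.5 * inside) * (1.0 + ad.cos(dist * (np.pi / cfg.r_c))),
                          (-1, 1))

        # stage 1: invariant atomic environments
        x = ad.take(P["embed"], np.asarray(mol.atomic_numbers, dtype=np.intp))
        for t in range(cfg.T):
            y = _linear(P, f"schnet{t}.in", x)
            w = self._filter(f"schnet{t}.filter", g, fcut)
            conv = ad.scatter_add(ad.take(y, j_idx) * w, i_idx, n)
            x = x + _mlp(P, f"schnet{t}.atom", conv)

        # stage 2: pair environments with angular momentum orders
        rhat = rvec * ad.reshape(dist ** -1.0, (-1, 1))
        omegas = []
        for lam in range(cfg.n_orders):
            f1 = _linear(P, f"orb{lam}.fac", x)
            w = self._filter(f"orb{lam}.filter", g, fcut)
            h = ssp(_linear(P, f"orb{lam}.mix",
                            ad.take(f1, i_idx) * ad.take(f1, j_idx) * w))
            x = x + _mlp(P, f"orb{lam}.atom", ad.scatter_add(h, i_idx, n))
            p_pair = _mlp(P, f"orb{lam}.pair", h)
            p_env = _mlp(P, f"orb{lam}.env", h)
            row = ad.scatter_add(p_env, i_idx, n)      # sum over pairs (i, *)
            col = ad.scatter_add(p_env, j_idx, n)      # sum over pairs (*, j)
            p = p_pair + ad.take(col, j_idx) + ad.take(row, i_idx) - 2.0 * p_env
            npair = len(i_idx)
            if lam == 0:
                om = ad.reshape(p, (npair, cfg.B, 1)) * constant(np.ones((1, 1, cfg.D)))
            else:
                pr = ad.reshape(p, (npair, cfg.B, 1)) * ad.reshape(rhat, (npair, 1, 3))
                om = ad.reshape(ad.reshape(pr, (npair * cfg.B, 3)) @ P[f"orb{lam}.dir"],
                                (npair, cfg.B, cfg.D))
            omegas.append(om)
        Omega = []
        acc = omegas[0]
        Omega.append(ad.reshape(acc, (len(i_idx), cfg.B * cfg.D)))
        for lam in range(1, cfg.n_orders):
            acc = acc * omegas[lam]
            Omega.append(ad.reshape(acc, (len(i_idx), cfg.B * cfg.D)))

        self.x, self.Omega = x, Omega
        self.H = self._assemble("head.h_off{}", "head.h_on{}", None)
        self.S = self._assemble("head.s_off{}", None, "head.s_on")
        self.E = ad.tsum(_mlp(P, "energy", x))

    # -- block assembly -------------------------------------------------
    def _assemble(self, off_fmt, on_fmt, s_on_key):
        P, cfg, mol, index = self.params, self.config, self.mol, self.index
        n_ao, M = index.n_orbitals, cfg.n_ao_max
        i_idx, j_idx = self.i_idx, self.j_idx

        off = None
        for l, om in enumerate(self.Omega):
            term = _linear(P, off_fmt.format(l), om)
            off = term if off is None else off + term

        # crop each pair block to (n_ao_i, n_ao_j) and scatter into the matrix
        rows, lidx, tgt = [], [], []
        counts = index.atom_counts
        offs = index.atom_offsets
        for k, (i, j) in enumerate(zip(i_idx, j_idx)):
            a = np.repeat(np.arange(counts[i]), counts[j])
            b = np.tile(np.arange(counts[j]), counts[i])
            rows.append(np.full(a.size, k))
            lidx.append(a * M + b)
            tgt.append((offs[i] + a) * n_ao + offs[j] + b)
        rows, lidx, tgt = (np.concatenate(v) if v else np.zeros(0, np.intp)
                           for v in (rows, lidx, tgt))
        vals = ad.take2(off, rows, lidx)
        Hflat = ad.scatter_add(vals, tgt, n_ao * n_ao)

        if on_fmt is not None:
            on = None
            for l, om in enumerate(self.Omega):
                term = _linear(P, on_fmt.format(l), om)
                on = term if on is None else on + term
            on_atom = ad.scatter_add(on, i_idx, mol.n_atoms)
        else:
            on_atom = ad.take(P[s_on_key], np.asarray(mol.atomic_numbers, np.intp))
        rows, lidx, tgt = [], [], []
        for i in range(mol.n_atoms):
            a = np.repeat(np.arange(counts[i]), counts[i])
            b = np.tile(np.arange(counts[i]), counts[i])
            rows.append(np.full(a.size, i))
            lidx.append(a * M + b)
            tgt.append((offs[i] + a) * n_ao + offs[i] + b)
        rows, lidx, tgt = (np.concatenate(v) for v in (rows, lidx, tgt))
        Hflat = Hflat + ad.scatter_add(ad.take2(on_atom, rows, lidx), tgt, n_ao * n_ao)

        Hmat = ad.reshape(Hflat, (n_ao, n_ao))
        return (Hmat + ad.transpose(Hmat)) * 0.5

    # -- user-facing results --------------------------------------------
    def forces(self) -> Tensor:
        """Differentiable force tensor -dE/dr."""
        return -ad.grad(self.E, [self.pos])[0]


@dataclasses.dataclass
class ElectronicPrediction:
    """Numpy view of one forward pass."""

    H: np.ndarray
    S: np.ndarray
    E: float
    F: np.ndarray


def predict(params: dict, config: ModelConfig, mol: Molecule,
            index: OrbitalIndex = None) -> ElectronicPrediction:
    fwd = Forward(params, config, mol, index)
    return ElectronicPrediction(H=fwd.H.value.copy(), S=fwd.S.value.copy(),
                                E=float(fwd.E.value), F=fwd.forces().value.copy())


# -- checkpointing ------------------------------------------------------

def save_checkpoint(path, params: dict, config: ModelConfig, basis: BasisSet = None,
                    extra: dict = None) -> None:
    arrays = {f"param:{k}": v.value for k, v in params.items()}
    meta = {"config": config.to_json(), "version": 1}
    if basis is not None:
        payload = {str(z): [{"l": s.l, "exp": list(map(float, s.exponents)),
                             "coef": list(map(float, s.coefficients))} for s in shells]
                   for z, shells in basis.shells.items()}
        meta["basis"] = json.dumps({"name": basis.name, "shells": payload})
    meta.update(extra or {})
    with open(path, "wb") as fh:        # keep the exact filename (no .npz suffix)
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns (params, config, basis-or-None, meta dict)."""
    from .chem import GaussianShell
    with np.load(path, allow_pickle=False) as fh:
        meta = json.loads(str(fh["meta"]))
        params = {k[len("param:"):]: tensor(fh[k]) for k in fh.files
                  if k.startswith("param:")}
    config = ModelConfig.from_json(meta["config"])
    basis = None
    if "basis" in meta:
        raw = json.loads(meta["basis"])
        basis = BasisSet({int(z): [GaussianShell(int(s["l"]), s["exp"], s["coef"])
                                   for s in entry]
                          for z, entry in raw["shells"].items()},
                         raw.get("name", "custom"))
    return params, config, basis, meta
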