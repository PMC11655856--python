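"""Fixed-point, Jacobian and stability analysis of the learned node dynamics.

Each (subject, region) node of a trained model defines an autonomous system
once the network input is set to zero and the encoded parameters are frozen:
under the velocity convention the state evolves as ``ẋ = f(x, θ)`` and a
fixed point is a root of ``f``; its stability is decided by the real parts
of the Jacobian eigenvalues.  The module also builds group-level attractor
brain maps and simulates BOLD forward from the learned system with or
without the disorder-specific components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import CohortDataset, Connectome
from .model import NDCVAE
from .nn import Tensor

__all__ = [
    "NodeDynamics",
    "FixedPointSet",
    "AttractorMap",
    "node_dynamics",
    "find_fixed_points",
    "attractor_maps",
    "compare_maps",
    "simulate_bold",
]


@dataclass
class NodeDynamics:
    """Frozen per-node dynamics ``f`` with its parameters.

    ``free`` marks the state coordinates being solved for; clamped
    coordinates (the specific block of a control node) are held at zero.
    ``convention`` is ``"velocity"`` (fixed point at f = 0, stable iff all
    Re λ < 0) or ``"map"`` (fixed point at f(x) = x, stable iff all
    |λ| < 1).
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    theta: np.ndarray  # concatenated (θ^r_sh, θ^r_sp, θ^s_sh, θ^s_sp)
    n_states: int
    u_ext: float = 0.0
    u_net: float = 0.0
    free: np.ndarray = None  # bool per state coordinate
    convention: str = "velocity"

    def __post_init__(self):
        if self.free is None:
            self.free = np.ones(2 * self.n_states, dtype=bool)
        self.free = np.asarray(self.free, dtype=bool)
        if self.convention not in ("velocity", "map"):
            raise ValueError(f"unknown convention {self.convention}")

    def _aug(self, x_full: np.ndarray) -> np.ndarray:
        return np.concatenate([x_full, self.theta, [self.u_ext, self.u_net]])

    def f_full(self, x_full: np.ndarray) -> np.ndarray:
        """The learned two-layer field on the full state vector."""
        h = np.maximum(self._aug(x_full) @ self.w1 + self.b1, 0.0)
        return h @ self.w2 + self.b2

    def embed(self, z: np.ndarray) -> np.ndarray:
        x_full = np.zeros(2 * self.n_states)
        x_full[self.free] = z
        return x_full

    def __call__(self, z: np.ndarray) -> np.ndarray:
        """Root-finding residual on the free coordinates."""
        out = self.f_full(self.embed(z))[self.free]
        if self.convention == "map":
            return out - z
        return out

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        """Jacobian of ``f`` at ``z`` via reverse-mode automatic
        differentiation through the field, restricted to free coordinates."""
        x_full = self.embed(np.asarray(z, dtype=float))
        n_free = int(self.free.sum())
        aug_pad = np.concatenate([np.zeros(2 * self.n_states), self.theta,
                                  [self.u_ext, self.u_net]])
        embed_mat = np.eye(2 * self.n_states, len(aug_pad))  # x block of x_aug
        jac = np.zeros((n_free, n_free))
        free_idx = np.where(self.free)[0]
        for row, i in enumerate(free_idx):
            xt = Tensor(x_full, requires_grad=True)
            full_aug = xt @ Tensor(embed_mat) + Tensor(aug_pad)
            h = (full_aug @ Tensor(self.w1) + Tensor(self.b1)).relu()
            out = h @ Tensor(self.w2) + Tensor(self.b2)
            seed = np.zeros(out.shape)
            seed[i] = 1.0
            out.backward(seed)
            jac[row] = xt.grad[free_idx]
        return jac

    def jacobian_fd(self, z: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """Central finite-difference Jacobian (agreement check)."""
        z = np.asarray(z, dtype=float)
        n = z.size
        jac = np.zeros((n, n))
        for j in range(n):
            zp, zm = z.copy(), z.copy()
            zp[j] += eps
            zm[j] -= eps
            fp = self.f_full(self.embed(zp))[self.free]
            fm = self.f_full(self.embed(zm))[self.free]
            jac[:, j] = (fp - fm) / (2 * eps)
        return jac


@dataclass
class FixedPointSet:
    roots: list[np.ndarray]
    jacobians: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    stable: list[bool]
    n_distinct: int
    diagnostics: str = ""


def node_dynamics(
    model: NDCVAE,
    theta_r_shared: np.ndarray,
    theta_r_specific: np.ndarray | None,
    theta_s_shared: np.ndarray,
    theta_s_specific: np.ndarray | None,
    u_ext: float = 0.0,
    convention: str = "velocity",
) -> NodeDynamics:
    """Freeze one node's learned dynamics at the given parameter values.

    For control nodes pass ``None`` for the specific blocks: their parameter
    slots are zero-padded and the specific state coordinates are clamped.
    """
    cfg = model.config
    is_control = theta_r_specific is None
    theta = np.concatenate(
        [
            theta_r_shared,
            np.zeros(cfg.m_region) if is_control else theta_r_specific,
            theta_s_shared,
            np.zeros(cfg.m_subject) if is_control else theta_s_specific,
        ]
    )
    free = np.ones(2 * cfg.n_states, dtype=bool)
    if is_control:
        free[cfg.n_states :] = False
    return NodeDynamics(
        w1=model.source_w1.weight.data,
        b1=model.source_w1.bias.data,
        w2=model.source_w2.weight.data,
        b2=model.source_w2.bias.data,
        theta=theta,
        n_states=cfg.n_states,
        u_ext=u_ext,
        u_net=0.0,
        free=free,
        convention=convention,
    )


def _fd_jacobian(fn, z: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    n = z.size
    jac = np.zeros((n, n))
    for j in range(n):
        zp, zm = z.copy(), z.copy()
        zp[j] += eps
        zm[j] -= eps
        jac[:, j] = (np.atleast_1d(fn(zp)) - np.atleast_1d(fn(zm))) / (2 * eps)
    return jac


def find_fixed_points(
    node,
    n_inits: int = 10,
    init_range: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
    tol: float = 1e-8,
    dedup_tol: float = 1e-4,
    n_dim: int | None = None,
) -> FixedPointSet:
    """Powell-hybrid root finding from uniform random initializations.

    ``node`` is a :class:`NodeDynamics` or any vector field callable (then
    ``n_dim`` gives its dimension and the Jacobian falls back to central
    finite differences).  Converged roots are deduplicated within
    ``dedup_tol`` in the max norm; an empty set (with a diagnostic) is
    returned if no start converges.
    """
    rng = np.random.default_rng(seed)
    if hasattr(node, "free"):
        n_free = int(node.free.sum())
    elif n_dim is not None:
        n_free = n_dim
    else:
        raise ValueError("n_dim required for a plain callable")
    convention = getattr(node, "convention", "velocity")
    fn = lambda z: np.atleast_1d(node(z))
    roots: list[np.ndarray] = []
    n_fail = 0
    for _ in range(n_inits):
        z0 = rng.uniform(*init_range, size=n_free)
        sol = optimize.root(fn, z0, method="hybr")
        if not sol.success or np.max(np.abs(fn(sol.x))) >= tol:
            n_fail += 1
            continue
        if not any(np.max(np.abs(sol.x - r)) < dedup_tol for r in roots):
            roots.append(sol.x)
    jacobians, eigenvalues, stable = [], [], []
    jac_of = node.jacobian if hasattr(node, "jacobian") else (
        lambda z: _fd_jacobian(fn, np.asarray(z, dtype=float))
    )
    for r in roots:
        jac = jac_of(r)
        eig = np.linalg.eigvals(jac)
        jacobians.append(jac)
        eigenvalues.append(eig)
        if convention == "velocity":
            stable.append(bool(np.all(eig.real < 0)))
        else:
            stable.append(bool(np.all(np.abs(eig) < 1)))
    diag = "" if roots else f"no convergence from {n_inits} starts"
    if n_fail and roots:
        diag = f"{n_fail}/{n_inits} starts failed to converge"
    return FixedPointSet(
        roots=roots,
        jacobians=jacobians,
        eigenvalues=eigenvalues,
        stable=stable,
        n_distinct=len(roots),
        diagnostics=diag,
    )


@dataclass
class AttractorMap:
    values: np.ndarray  # (n_regions,) group-mean fixed-point coordinate
    counts: np.ndarray  # (n_regions,) subjects contributing per region
    group: str
    encoder: str
    state_index: int


def attractor_maps(
    model: NDCVAE,
    dataset: CohortDataset,
    encoded: dict,
    state_index: int,
    group: str,
    encoder: str = "shared",
    n_inits: int = 10,
    seed: int = 0,
) -> AttractorMap:
    """Region-wise group means of each node's fixed-point coordinate.

    For multistable nodes the root nearest the node's mean encoded state is
    used.  Missing roots are excluded from the mean, with per-region counts
    reported.
    """
    cfg = model.config
    is_pat = encoded["is_patient"]
    subjects = np.where(is_pat if group == "patient" else ~is_pat)[0]
    if subjects.size == 0:
        raise ValueError(f"no subjects in group {group!r}")
    if encoder == "specific" and group == "control":
        raise ValueError("specific states are undefined for controls")
    coord = state_index if encoder == "shared" else cfg.n_states + state_index
    sums = np.zeros(dataset.n_regions)
    counts = np.zeros(dataset.n_regions, dtype=int)
    for s in subjects:
        for r in range(dataset.n_regions):
            spec_args = (
                (encoded["specific.region"][s, r], encoded["specific.subject"][s])
                if is_pat[s]
                else (None, None)
            )
            node = node_dynamics(
                model,
                encoded["shared.region"][s, r],
                spec_args[0],
                encoded["shared.subject"][s],
                spec_args[1],
            )
            fps = find_fixed_points(node, n_inits=n_inits, seed=seed + 97 * s + r)
            if fps.n_distinct == 0:
                continue
            traj_mean = np.concatenate(
                [
                    encoded["shared.states"][s, r].mean(axis=0),
                    encoded["specific.states"][s, r].mean(axis=0),
                ]
            )[node.free]
            best = min(
                fps.roots, key=lambda root: np.linalg.norm(root - traj_mean)
            )
            full = node.embed(best)
            sums[r] += full[coord]
            counts[r] += 1
    values = np.divide(sums, counts, out=np.full_like(sums, np.nan), where=counts > 0)
    return AttractorMap(
        values=values, counts=counts, group=group, encoder=encoder,
        state_index=state_index,
    )


def compare_maps(
    map_a: np.ndarray,
    map_b: np.ndarray,
    distances: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation of two region maps with a spatial-surrogate p.

    The null preserves the spatial autocorrelation of ``map_a`` via
    variogram-matched surrogates; p is the rank of |r| in the surrogate |r|
    distribution (add-one convention).
    """
    from .spatial_null import surrogate_maps

    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.std() == 0 or map_b.std() == 0:
        raise ValueError("constant map: correlation undefined")
    r_obs = stats.pearsonr(map_a, map_b)[0]
    surr = surrogate_maps(map_a, distances, n=n_surrogates, seed=seed)
    r_null = np.array([stats.pearsonr(s, map_b)[0] for s in surr])
    p = (1.0 + np.sum(np.abs(r_null) >= np.abs(r_obs))) / (1.0 + n_surrogates)
    return float(r_obs), float(p)


def simulate_bold(
    model: NDCVAE,
    encoded: dict,
    subject_index: int,
    connectome: Connectome,
    include_specific: bool = True,
    n_sim: int = 100,
    n_time: int | None = None,
    seed: int = 0,
    sigma_s: float | None = None,
    sigma_o: float | None = None,
) -> np.ndarray:
    """Forward-Euler simulation of a subject's full node systems.

    The network input is closed through the decoded observations of the
    other regions at the previous step.  ``include_specific=False`` zeroes
    the specific states and parameters (for controls this changes nothing:
    their specific slots are zero by construction).  Returns an array of
    shape (n_sim, n_regions, n_time).
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    cfg = model.config
    n_regions = encoded["shared.region"].shape[1]
    n_t = n_time or encoded["shared.states"].shape[2]
    rng = np.random.default_rng(seed)
    sig_s = model.sigma_s if sigma_s is None else sigma_s
    sig_o = model.sigma_o if sigma_o is None else sigma_o
    s = subject_index
    is_pat = bool(encoded["is_patient"][s])
    use_spec = include_specific and is_pat
    thr_sh = encoded["shared.region"][s]  # (n_regions, m_r)
    thr_sp = encoded["specific.region"][s] if use_spec else np.zeros_like(thr_sh)
    ths_sh = np.tile(encoded["shared.subject"][s], (n_regions, 1))
    ths_sp = (
        np.tile(encoded["specific.subject"][s], (n_regions, 1))
        if use_spec
        else np.zeros((n_regions, cfg.m_subject))
    )
    w1, b1 = model.source_w1.weight.data, model.source_w1.bias.data
    w2, b2 = model.source_w2.weight.data, model.source_w2.bias.data
    w_dec, b_dec = model.decoder.weight.data[:, 0], float(model.decoder.bias.data[0])
    x0 = np.concatenate(
        [
            encoded["shared.states"][s, :, 0, :],
            encoded["specific.states"][s, :, 0, :] if use_spec
            else np.zeros((n_regions, cfg.n_states)),
        ],
        axis=1,
    )
    out = np.empty((n_sim, n_regions, n_t))
    conn_w = connectome.weights
    for k in range(n_sim):
        x = x0.copy()
        y_prev = x @ w_dec + b_dec
        for t in range(n_t):
            u = conn_w @ y_prev
            aug = np.concatenate(
                [x, thr_sh, thr_sp, ths_sh, ths_sp,
                 np.zeros((n_regions, 1)), u[:, None]],
                axis=1,
            )
            vel = np.maximum(aug @ w1 + b1, 0.0) @ w2 + b2
            x = x + cfg.euler_step * vel
            if sig_s > 0:
                x = x + np.sqrt(cfg.euler_step) * sig_s * rng.normal(size=x.shape)
            if not use_spec:
                x[:, cfg.n_states :] = 0.0
            y = x @ w_dec + b_dec
            if sig_o > 0:
                y = y + sig_o * rng.normal(size=y.shape)
            out[k, :, t] = y
            y_prev = y
    return out
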