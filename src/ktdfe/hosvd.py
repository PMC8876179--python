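"""Classical higher-order SVD (Tucker form) with a full core.

For each mode the factor matrix holds the left singular vectors of that
mode's unfolding, ordered by descending singular value; the core is the
all-mode projection of the input onto the factor transposes, so the full
decomposition reconstructs the input exactly (up to round-off).

Sign convention: every factor column is flipped so that its largest-magnitude
entry is positive (ties broken by lowest index).  SVD leaves column signs
undetermined; the convention makes runs reproducible.  Downstream P-values
are invariant to these signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelTensor, ModeRoles

__all__ = ["HOSVDResult", "mode_unfold", "mode_refold", "hosvd", "reconstruct", "check_symmetry"]


def mode_unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Unfold a tensor along one mode into a ``shape[mode] x rest`` matrix."""
    tensor = np.asarray(tensor)
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} invalid for order-{tensor.ndim} tensor")
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def mode_refold(matrix: np.ndarray, mode: int, shape: tuple) -> np.ndarray:
    """Inverse of :func:`mode_unfold` for the given full tensor shape."""
    shape = tuple(shape)
    if not 0 <= mode < len(shape):
        raise ValueError(f"mode {mode} invalid for shape {shape}")
    moved = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(np.asarray(matrix).reshape(moved), 0, mode)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(u), axis=0)  # argmax takes the lowest index on ties
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


@dataclass
class HOSVDResult:
    factors: list  # one (M_mode x M_mode) orthogonal matrix per mode
    core: np.ndarray  # same shape as the input
    mode_roles: ModeRoles | None = None
    singular_values: list = field(default_factory=list)

    @property
    def shape(self) -> tuple:
        return self.core.shape

    def factor(self, mode: int) -> np.ndarray:
        return self.factors[mode]


def hosvd(tensor) -> HOSVDResult:
    """Decompose a tensor (or :class:`KernelTensor`) into factors + core."""
    mode_roles = None
    if isinstance(tensor, KernelTensor):
        mode_roles = tensor.mode_roles
        tensor = tensor.values
    x = np.asarray(tensor, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("HOSVD input must be finite")
    if np.linalg.norm(x) == 0:
        raise ValueError("HOSVD input is identically zero")
    factors, svals = [], []
    for mode in range(x.ndim):
        u, s, _ = np.linalg.svd(mode_unfold(x, mode), full_matrices=True)
        factors.append(_fix_signs(u))
        svals.append(s)
    core = x
    for mode, u in enumerate(factors):
        # contract mode with u's rows: core <- core x_mode u^T
        core = np.moveaxis(np.tensordot(core, u, axes=(mode, 0)), -1, mode)
    return HOSVDResult(factors=factors, core=core, mode_roles=mode_roles, singular_values=svals)


def reconstruct(result: HOSVDResult) -> np.ndarray:
    """All-mode product of the core with the factors; equals the input."""
    x = result.core
    if x.ndim != len(result.factors):
        raise ValueError("core order and factor count disagree")
    for mode, u in enumerate(result.factors):
        if u.shape[0] != x.shape[mode]:
            raise ValueError(f"factor for mode {mode} does not match core shape")
        x = np.moveaxis(np.tensordot(x, u, axes=(mode, 1)), -1, mode)
    return x


def _column_sign_dev(a: np.ndarray, b: np.ndarray) -> float:
    """Max columnwise deviation between two factors, allowing per-column sign."""
    dev = 0.0
    for col in range(a.shape[1]):
        d = min(
            np.max(np.abs(a[:, col] - b[:, col])),
            np.max(np.abs(a[:, col] + b[:, col])),
        )
        dev = max(dev, float(d))
    return dev


def check_symmetry(result: HOSVDResult) -> dict:
    """Diagnostics for the paired-sample-mode structure of a kernel HOSVD.

    Returns a dict with:

    - ``factor_dev``: max deviation between each sample-mode factor and its
      conjugate-mode factor, up to column signs.  The Gram construction makes
      the two unfoldings column permutations of each other, so this is ~0.
    - ``core_full_swap_dev``: max |G - G'| where G' swaps *all* sample modes
      with their conjugates simultaneously — guaranteed ~0 for any kernel.
    - ``core_single_swap_dev``: max over single-pair swaps (one sample mode
      exchanged with its conjugate, the others fixed).  For m >= 2 this extra
      symmetry is not implied by the Gram construction and can be nonzero;
      reported for inspection.
    """
    if result.mode_roles is None:
        raise ValueError("symmetry check needs mode_roles")
    m = result.mode_roles.m
    factor_dev = 0.0
    for s in range(1, m + 1):
        factor_dev = max(factor_dev, _column_sign_dev(result.factors[s], result.factors[s + m]))
    g = result.core
    perm_full = [0] + list(range(m + 1, 2 * m + 1)) + list(range(1, m + 1))
    full_dev = float(np.max(np.abs(g - np.transpose(g, perm_full)))) if m else 0.0
    single_dev = 0.0
    for s in range(1, m + 1):
        perm = list(range(g.ndim))
        perm[s], perm[s + m] = perm[s + m], perm[s]
        single_dev = max(single_dev, float(np.max(np.abs(g - np.transpose(g, perm)))))
    scale = float(np.linalg.norm(g))
    return {
        "factor_dev": factor_dev,
        "core_full_swap_dev": full_dev,
        "core_single_swap_dev": single_dev,
        "core_norm": scale,
    }
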