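"""Sample-similarity kernels and the stacked kernel tensor.

The central memory trick: instead of decomposing K feature-by-sample arrays
(whose feature counts N_k can reach ~7e5), each block is reduced to a linear
Gram tensor over its samples, ``k(j..., j'...) = sum_i x[i, j...] x[i, j'...]``,
and the K Gram tensors are stacked into a single order-(2m+1) tensor of shape
``K x M_1 x ... x M_m x M_1 x ... x M_m`` — whose size never depends on any
N_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .omics import MultiOmicsBlock, validate_set

__all__ = ["KernelSpec", "ModeRoles", "KernelTensor", "linear_kernel", "stack_kernels"]

_SUPPORTED_KERNELS = ("linear",)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice.  Any kernel added here must produce, per omics slice, a
    tensor symmetric under swapping the sample tuple with its conjugate and
    positive semi-definite when flattened to (prod M_s) x (prod M_s)."""

    kind: str = "linear"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _SUPPORTED_KERNELS:
            raise ValueError(f"unsupported kernel kind {self.kind!r}; supported: {_SUPPORTED_KERNELS}")


@dataclass(frozen=True)
class ModeRoles:
    """Mode layout of a kernel tensor: mode 0 = omics, modes 1..m = sample
    modes, modes m+1..2m = their conjugates."""

    m: int

    @property
    def omics_mode(self) -> int:
        return 0

    @property
    def sample_modes(self) -> tuple:
        return tuple(range(1, self.m + 1))

    @property
    def conjugate_modes(self) -> tuple:
        return tuple(range(self.m + 1, 2 * self.m + 1))


@dataclass
class KernelTensor:
    values: np.ndarray  # shape (K, M_1..M_m, M_1..M_m)
    mode_roles: ModeRoles
    omics_ids: list = field(default_factory=list)

    def __post_init__(self):
        m = self.mode_roles.m
        if self.values.ndim != 2 * m + 1:
            raise ValueError(f"expected order {2*m+1} tensor, got {self.values.ndim}")
        if self.values.shape[1 : m + 1] != self.values.shape[m + 1 :]:
            raise ValueError("sample modes and conjugate modes disagree in size")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def sample_shape(self) -> tuple:
        return self.values.shape[1 : self.mode_roles.m + 1]


def linear_kernel(block) -> np.ndarray:
    """Gram tensor of one block: entry (j..., j'...) = sum_i x[i,j...]x[i,j'...].

    Returns an array of shape ``M_1 x .. x M_m x M_1 x .. x M_m``.  For a
    standardized block every diagonal entry equals N_k by construction.
    """
    x = block.values if isinstance(block, MultiOmicsBlock) else np.asarray(block, float)
    if x.ndim < 2 or x.shape[0] == 0:
        raise ValueError("linear kernel needs a non-empty feature mode")
    if not np.isfinite(x).all():
        raise ValueError("linear kernel input must be finite")
    sample_shape = x.shape[1:]
    flat = x.reshape(x.shape[0], -1)
    gram = flat.T @ flat
    gram = (gram + gram.T) / 2.0  # enforce exact symmetry against round-off
    return gram.reshape(*sample_shape, *sample_shape)


def stack_kernels(tset, spec: KernelSpec | None = None) -> KernelTensor:
    """Stack per-omics kernels into the order-(2m+1) tensor HOSVD consumes."""
    spec = spec or KernelSpec()
    violations = validate_set(tset)
    if violations:
        raise ValueError("cannot stack kernels: " + "; ".join(violations))
    blocks = tset.blocks
    slices = [linear_kernel(b) for b in blocks]
    values = np.stack(slices, axis=0)
    m = blocks[0].n_sample_modes
    return KernelTensor(values=values, mode_roles=ModeRoles(m), omics_ids=[b.omics_id for b in blocks])
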