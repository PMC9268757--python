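"""Compact CNN architecture notation and the conv-layer complexity estimate.

Architectures are named "C<f1>-<f2>…/D<d1>…": conv filter counts, then dense
unit counts, e.g. ``C64-128/D64`` = Conv2D(64, 128) → Dense(64) → Dense(11,
softmax).  The grid of nine such architectures spans one to three conv
layers between 64 and 512 filters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ArchSpec",
    "parse_arch",
    "format_arch",
    "ComplexityEstimate",
    "estimate_complexity",
    "STANDARD_ARCHS",
]

#: The nine-architecture comparison grid.
STANDARD_ARCHS: tuple[str, ...] = (
    "C64/D64",
    "C64-64/D64",
    "C128/D128",
    "C64-128/D64",
    "C128-64/D64",
    "C64-128-64/D64",
    "C64-128-64/D128",
    "C128-256-128/D128",
    "C512-256-128/D128",
)

_ARCH_RE = re.compile(r"^C(\d+(?:-\d+)*)/D(\d+(?:-\d+)*)$")


@dataclass(frozen=True)
class ArchSpec:
    """Parsed CNN architecture.

    ``conv_filters`` and ``dense_units`` are the hidden layer widths; the
    output layer is fixed at 11 softmax units (one per prompt).  Convolutions
    are ``kernel_size`` × ``kernel_size``, stride 1, no padding, no pooling.
    """

    conv_filters: tuple[int, ...]
    dense_units: tuple[int, ...]
    conv_activation: str = "relu"
    dense_activation: str = "tanh"
    output_units: int = 11
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if not self.conv_filters or not self.dense_units:
            raise ValueError("need at least one conv and one dense layer")
        if any(f < 1 for f in self.conv_filters + self.dense_units):
            raise ValueError("layer widths must be positive")
        if self.conv_activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation: {self.conv_activation!r}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd and positive")
        object.__setattr__(self, "conv_filters", tuple(self.conv_filters))
        object.__setattr__(self, "dense_units", tuple(self.dense_units))

    @property
    def abbreviation(self) -> str:
        return format_arch(self)

    def output_side(self, input_side: int) -> int:
        """Spatial side of the last conv output under valid convolutions."""
        side = input_side - len(self.conv_filters) * (self.kernel_size - 1)
        if side < 1:
            raise ValueError(
                f"input side {input_side} too small for "
                f"{len(self.conv_filters)} valid {self.kernel_size}×"
                f"{self.kernel_size} convolutions"
            )
        return side

    def parameter_count(self, input_side: int) -> int:
        """Closed-form trainable parameter count for a C×C input."""
        k = self.kernel_size
        total = 0
        prev = 1
        for f in self.conv_filters:
            total += k * k * prev * f + f
            prev = f
        fan_in = self.output_side(input_side) ** 2 * self.conv_filters[-1]
        for d in self.dense_units:
            total += fan_in * d + d
            fan_in = d
        total += fan_in * self.output_units + self.output_units
        return total


def parse_arch(abbrev: str, conv_activation: str = "relu",
               kernel_size: int = 3) -> ArchSpec:
    """Parse an architecture abbreviation like ``C64-128/D64``."""
    m = _ARCH_RE.match(abbrev.strip())
    if m is None:
        token = abbrev.split("/")[0] if abbrev else abbrev
        raise ValueError(
            f"malformed architecture string {abbrev!r} (offending token "
            f"{token!r}); expected C<n>(-<n>)*/D<n>(-<n>)*"
        )
    conv = tuple(int(t) for t in m.group(1).split("-"))
    dense = tuple(int(t) for t in m.group(2).split("-"))
    return ArchSpec(conv_filters=conv, dense_units=dense,
                    conv_activation=conv_activation, kernel_size=kernel_size)


def format_arch(arch: ArchSpec) -> str:
    """Inverse of :func:`parse_arch`: the compact abbreviation string."""
    conv = "-".join(str(f) for f in arch.conv_filters)
    dense = "-".join(str(d) for d in arch.dense_units)
    return f"C{conv}/D{dense}"


@dataclass(frozen=True)
class ComplexityEstimate:
    """Operation counts and parameter memory of one architecture."""

    per_layer_ops: tuple[tuple[str, int], ...]
    total_ops: int
    parameter_count: int
    parameter_bytes: int


def estimate_complexity(arch: ArchSpec, input_side: int) -> ComplexityEstimate:
    """Estimate multiply counts layer by layer for a C × C input.

    Conv layer l costs k² × N² × nF^(l−1) × nF^l multiplies with nF^0 = 1 and
    N fixed at the input side (the input is square and, with small kernels,
    the conv outputs stay close to N × N, so N is used for every conv layer).
    A dense layer costs fan_in × fan_out; parameters are 4 bytes each
    (float32).
    """
    k = arch.kernel_size
    per_layer: list[tuple[str, int]] = []
    prev = 1
    for f in arch.conv_filters:
        per_layer.append((f"Conv2D-{f}", k * k * input_side ** 2 * prev * f))
        prev = f
    fan_in = arch.output_side(input_side) ** 2 * arch.conv_filters[-1]
    for d in arch.dense_units:
        per_layer.append((f"Dense-{d}", fan_in * d))
        fan_in = d
    per_layer.append((f"Dense-{arch.output_units}",
                      fan_in * arch.output_units))
    total = sum(ops for _, ops in per_layer)
    n_params = arch.parameter_count(input_side)
    return ComplexityEstimate(
        per_layer_ops=tuple(per_layer),
        total_ops=total,
        parameter_count=n_params,
        parameter_bytes=4 * n_params,
    )
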