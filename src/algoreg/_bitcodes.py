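"""Low-level self-delimiting bit codes.

Bitstrings are plain Python ``str`` objects over the characters ``'0'``/``'1'``
(short enough everywhere in this package that the readability is worth it).
The Elias gamma code provides the self-delimiting integer headers; fixed-width
fields cover values whose range is already known from the header.
"""

from __future__ import annotations


class InvalidCodeError(ValueError):
    """A bitstring does not begin with a valid code word."""


def elias_gamma(n: int) -> str:
    """Elias gamma code word for an integer ``n >= 1`` (prefix-free)."""
    if n < 1:
        raise ValueError(f"Elias gamma is defined for n >= 1, got {n}")
    b = bin(n)[2:]
    return "0" * (len(b) - 1) + b


def elias_gamma_len(n: int) -> int:
    """Length in bits of ``elias_gamma(n)`` without building the string."""
    if n < 1:
        raise ValueError(f"Elias gamma is defined for n >= 1, got {n}")
    return 2 * n.bit_length() - 1


def fixed_width(value: int, size: int) -> str:
    """Encode ``value`` in ``ceil(log2 size)`` bits; zero bits when size == 1."""
    if not 0 <= value < size:
        raise ValueError(f"value {value} out of range for size {size}")
    w = (size - 1).bit_length()
    return format(value, f"0{w}b") if w else ""


def fixed_width_len(size: int) -> int:
    return (size - 1).bit_length()


class BitReader:
    """Sequential reader over a bitstring; raises InvalidCodeError on underrun."""

    def __init__(self, bits: str):
        self.bits = bits
        self.pos = 0

    def take(self, n: int) -> str:
        if self.pos + n > len(self.bits):
            raise InvalidCodeError("truncated code word")
        out = self.bits[self.pos : self.pos + n]
        self.pos += n
        return out

    def read_gamma(self) -> int:
        zeros = 0
        while True:
            bit = self.take(1)
            if bit == "1":
                break
            zeros += 1
        rest = self.take(zeros)
        return int("1" + rest, 2)

    def read_fixed(self, size: int) -> int:
        w = fixed_width_len(size)
        if w == 0:
            return 0
        value = int(self.take(w), 2)
        if value >= size:
            raise InvalidCodeError(f"fixed-width value {value} out of range {size}")
        return value
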