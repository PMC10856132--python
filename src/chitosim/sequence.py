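"""Chitosan sequence model.

A chitosan chain is a beta-1,4-linked copolymer of glucosamine (GlcN) and
N-acetylglucosamine (GlcNAc). Its sequence is described by three parameters:

* DP — degree of polymerization, the number of monomer units;
* DA — degree of acetylation, the fraction of GlcNAc units;
* PA — pattern of acetylation, the arrangement of GlcNAc along the chain
  (block, alternating, random, or an explicit custom pattern).

Index 1 is the non-reducing end of the chain. Pattern strings use
``G`` = GlcN and ``A`` = GlcNAc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GLCN = "GlcN"
GLCNAC = "GlcNAc"
PATTERNS = ("block", "alternating", "random", "custom")

#: default placement of the acetylated block (1-based, inclusive) when a
#: block pattern is requested: the GlcNAc run sits at the reducing end.
BLOCK_AT_REDUCING_END = True


@dataclass(frozen=True)
class MonomerUnit:
    kind: str  # GlcN | GlcNAc
    index: int  # 1-based position, index 1 = non-reducing end

    def __post_init__(self):
        if self.kind not in (GLCN, GLCNAC):
            raise ValueError(f"unknown monomer kind {self.kind!r}")
        if self.index < 1:
            raise ValueError("monomer index is 1-based")


@dataclass(frozen=True)
class ChitosanSequence:
    units: tuple[MonomerUnit, ...]
    pattern_label: str

    def __post_init__(self):
        if len(self.units) < 2:
            raise ValueError("a chain needs DP >= 2")
        if self.pattern_label not in PATTERNS:
            raise ValueError(f"unknown pattern label {self.pattern_label!r}")
        for i, u in enumerate(self.units, start=1):
            if u.index != i:
                raise ValueError(f"unit {i} carries index {u.index}")

    @property
    def dp(self) -> int:
        return len(self.units)

    @property
    def n_acetylated(self) -> int:
        return sum(u.kind == GLCNAC for u in self.units)

    @property
    def da(self) -> float:
        return self.n_acetylated / self.dp

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(u.kind for u in self.units)

    def to_pattern_string(self) -> str:
        return "".join("A" if u.kind == GLCNAC else "G" for u in self.units)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_pattern_string()


def _units(kinds) -> tuple[MonomerUnit, ...]:
    return tuple(MonomerUnit(k, i) for i, k in enumerate(kinds, start=1))


def from_pattern_string(pattern: str) -> ChitosanSequence:
    """Build a sequence from a ``G``/``A`` string (e.g. ``"GGGGGAAAAA"``)."""
    pattern = pattern.strip().upper()
    bad = set(pattern) - {"G", "A"}
    if bad:
        raise ValueError(f"pattern string may contain only G/A, got {sorted(bad)}")
    kinds = [GLCNAC if c == "A" else GLCN for c in pattern]
    return ChitosanSequence(_units(kinds), "custom")


def make_sequence(dp: int, da: float, pattern: str,
                  seed: int | None = None) -> ChitosanSequence:
    """Generate a chitosan sequence with the requested DP, DA and pattern.

    Parameters
    ----------
    dp : int
        Degree of polymerization (>= 2).
    da : float
        Degree of acetylation in [0, 1]. For the deterministic block and
        alternating patterns ``da * dp`` must be an integer.
    pattern : {"block", "alternating", "random"}
        Block places the GlcNAc units as one contiguous run at the reducing
        end; alternating interleaves them as evenly as possible (strictly
        alternating at DA = 0.5); random places them uniformly at random
        (requires ``seed``). For full control use
        :func:`from_pattern_string`.
    seed : int, optional
        Required for the random pattern; same seed gives the identical
        sequence.
    """
    if dp < 2:
        raise ValueError(f"dp must be >= 2, got {dp}")
    if not 0.0 <= da <= 1.0:
        raise ValueError(f"da must be in [0, 1], got {da}")
    if pattern not in ("block", "alternating", "random"):
        raise ValueError(f"pattern must be block|alternating|random, got {pattern!r}")

    n_ac_f = da * dp
    n_ac = int(round(n_ac_f))
    if pattern in ("block", "alternating") and abs(n_ac_f - n_ac) > 1e-9:
        raise ValueError(
            f"da*dp = {n_ac_f} is not an integer; the {pattern} pattern needs an "
            f"integral number of GlcNAc units")

    if pattern == "block":
        kinds = [GLCN] * dp
        if BLOCK_AT_REDUCING_END:
            for i in range(dp - n_ac, dp):
                kinds[i] = GLCNAC
        else:  # pragma: no cover - alternative placement
            for i in range(n_ac):
                kinds[i] = GLCNAC
    elif pattern == "alternating":
        # spread n_ac acetylated units as evenly as possible; at DA 0.5 this
        # is strict alternation starting with GlcN at the non-reducing end
        kinds = [GLCN] * dp
        if n_ac:
            positions = (np.floor((np.arange(n_ac) + 1) * dp / n_ac) - 1).astype(int)
            for p in positions:
                kinds[p] = GLCNAC
    else:  # random
        if seed is None:
            raise ValueError("the random pattern requires a seed")
        n_ac = int(round(n_ac_f))
        rng = np.random.default_rng(seed)
        chosen = rng.choice(dp, size=n_ac, replace=False)
        kinds = [GLCN] * dp
        for p in chosen:
            kinds[p] = GLCNAC

    seq = ChitosanSequence(_units(kinds), pattern)
    if pattern in ("block", "alternating") and seq.n_acetylated != n_ac:
        raise AssertionError("composition bookkeeping error")
    return seq


def composition(seq: ChitosanSequence) -> tuple[int, int, float]:
    """Return (n_GlcN, n_GlcNAc, DA) of a sequence."""
    n_ac = seq.n_acetylated
    return seq.dp - n_ac, n_ac, n_ac / seq.dp
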