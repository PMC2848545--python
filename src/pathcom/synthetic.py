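"""Synthetic probe-level datasets with planted occupancy structure.

Emulates a low-density tiling ChIP-chip design: ~20,000 probes of which
one TSS probe per gene (~5,743 genes) and a set of tail-to-tail intergenic
probes expected to be factor-free.  Each gene gets a true occupancy vector
near its H/L archetype; probe signals are background times a linear gain
in true occupancy (with a factor-specific crosslinking scale that the
percent scaling is designed to cancel) under multiplicative lognormal
noise, the standard noise model for array intensities.  Deterministic
under a seed, so every downstream module is testable without downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mechanisms import FactorOrder

__all__ = [
    "SyntheticConfig",
    "default_codes",
    "archetype_patterns",
    "generate_probe_dataset",
    "generate_group_medians",
]

#: Canonical archetype occupancies (percent) for low / high groups, well
#: clear of the 10% grouping cutoff on either side.
ARCHETYPE_L = 5.0
ARCHETYPE_H = 40.0

#: Factor codes in the in-vitro assembly order used throughout: TBP (T),
#: TFIIB (B), pol II (P), TFIIF (F), TFIIE (E), TFIIH (H).
FULL_CODE_ORDER = ("T", "B", "P", "F", "E", "H")
_DEFAULTS_BY_N = {1: "T", 2: "TB", 3: "TBP", 4: "TBPH", 5: "TBPFH", 6: "TBPFEH"}


def default_codes(n_factors: int) -> tuple[str, ...]:
    """Default factor codes for n factors, following the assembly order."""
    try:
        return tuple(_DEFAULTS_BY_N[n_factors])
    except KeyError:
        raise ValueError(f"no default codes for {n_factors} factors") from None


def archetype_patterns(n_factors: int) -> list[tuple[str, ...]]:
    """All 2^n H/L patterns in canonical (L-first) order."""
    return list(product("LH", repeat=n_factors))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generated dataset.

    Defaults mirror the emulated design: ~20,000 probes total, one TSS
    probe for each of 5,743 genes, 2,000 T-T intergenic probes, two
    replicates each for factor IPs and the background strain, and a fold
    gain placing the strongest planted occupancies near the top percentile
    so the percent scaling is non-degenerate.
    """

    n_factors: int = 3
    codes: tuple[str, ...] | None = None
    archetypes: Mapping[str, float] = field(
        default_factory=lambda: {"L": ARCHETYPE_L, "H": ARCHETYPE_H}
    )
    genes_per_pattern: Mapping[tuple[str, ...], int] | int | None = None
    n_genes_total: int = 5743
    n_probes_total: int = 20000
    n_tt_probes: int = 2000
    factor_replicates: int = 2
    background_replicates: int = 2
    crosslink_scale: Mapping[str, float] | float = 1.0
    sigma: float = 0.1
    background_level: float = 100.0
    fold_gain: float = 10.0       # fold at 100% true occupancy (top promoters
                                  # enrich ~10-fold over background)
    occ_jitter: float = 1.0       # sd (percent) of gene-level deviation
    anchor_fraction: float = 0.02  # fraction of probes planted fully occupied;
                                   # twice the percentile rank, so the p99
                                   # estimate is centered in the anchor block
    seed: int = 0

    def resolved_codes(self) -> tuple[str, ...]:
        codes = self.codes if self.codes is not None else default_codes(self.n_factors)
        if len(codes) != self.n_factors:
            raise ValueError("codes length does not match n_factors")
        FactorOrder(codes)  # validates
        return tuple(codes)

    def resolved_genes_per_pattern(self) -> dict[tuple[str, ...], int]:
        patterns = archetype_patterns(self.n_factors)
        gpp = self.genes_per_pattern
        if gpp is None:
            base, extra = divmod(self.n_genes_total, len(patterns))
            return {p: base + (1 if i < extra else 0) for i, p in enumerate(patterns)}
        if isinstance(gpp, int):
            return {p: gpp for p in patterns}
        out = {tuple(k): int(v) for k, v in gpp.items()}
        if any(v < 0 for v in out.values()):
            raise ValueError("gene counts must be nonnegative")
        return out

    def kappa(self, code: str) -> float:
        if isinstance(self.crosslink_scale, Mapping):
            return float(self.crosslink_scale[code])
        return float(self.crosslink_scale)

    def validate(self) -> None:
        codes = self.resolved_codes()
        n_genes = sum(self.resolved_genes_per_pattern().values())
        if n_genes == 0:
            raise ValueError("no genes configured")
        if self.n_probes_total < n_genes + self.n_tt_probes:
            raise ValueError(
                f"{self.n_probes_total} probes cannot hold {n_genes} TSS + "
                f"{self.n_tt_probes} T-T probes"
            )
        if self.sigma < 0 or self.background_level <= 0 or self.fold_gain <= 0:
            raise ValueError("sigma >= 0 and positive background/gain required")
        for c in codes:
            if self.kappa(c) <= 0:
                raise ValueError(f"crosslinking scale for {c!r} must be positive")
        lo, hi = self.archetypes["L"], self.archetypes["H"]
        if not (0 <= lo < 10 <= hi <= 100):
            raise ValueError("archetypes must satisfy L < 10 <= H (percent)")


def generate_probe_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a raw probe table with planted per-gene occupancies.

    Returns a DataFrame indexed by ``probe_id`` with ``probe_class``,
    ``gene_id``, one ``FACTOR_rep#`` column per factor replicate, one
    ``BG_rep#`` column per background replicate, and (for reference, not
    consumed by preprocessing) the planted truth in ``true_occ_FACTOR``
    and ``true_pattern`` columns.  Byte-identical under identical
    config + seed.
    """
    config.validate()
    codes = config.resolved_codes()
    gpp = config.resolved_genes_per_pattern()
    rng = np.random.default_rng(config.seed)

    rows_pattern: list[str] = []
    for pattern in archetype_patterns(config.n_factors):
        rows_pattern += [",".join(pattern)] * gpp.get(pattern, 0)
    n_genes = len(rows_pattern)
    n_other = config.n_probes_total - n_genes - config.n_tt_probes

    probe_class = (
        ["TSS"] * n_genes
        + ["TT_intergenic"] * config.n_tt_probes
        + ["other"] * n_other
    )
    n_probes = len(probe_class)
    gene_ids = [f"gene{str(i + 1).zfill(4)}" for i in range(n_genes)]
    probe_ids = [f"probe{str(i + 1).zfill(5)}" for i in range(n_probes)]

    # True occupancy: archetype value jittered per gene, kept on its side
    # of the grouping cutoff.  T-T probes are factor-free; a small anchor
    # tail of fully occupied non-gene loci pins the per-factor 99th
    # percentile to the generator's fold gain, so the percent scaling
    # recovers planted occupancies as the identity map at zero noise.
    true_occ = np.zeros((n_probes, len(codes)))
    n_anchor = min(int(math.ceil(config.anchor_fraction * n_probes)), max(n_other, 0))
    if n_anchor:
        true_occ[n_probes - n_anchor :, :] = 100.0
    for j in range(len(codes)):
        letters = np.array([p.split(",")[j] for p in rows_pattern])
        base = np.where(letters == "H", config.archetypes["H"], config.archetypes["L"])
        jit = rng.normal(0.0, config.occ_jitter, size=n_genes)
        occ = base + jit
        occ = np.where(letters == "H", np.clip(occ, 12.0, 100.0), np.clip(occ, 0.0, 8.0))
        true_occ[:n_genes, j] = occ

    data: dict[str, np.ndarray] = {}
    for j, code in enumerate(codes):
        gain = config.kappa(code) * (config.fold_gain - 1.0)
        mean_fold = 1.0 + gain * true_occ[:, j] / 100.0
        for r in range(1, config.factor_replicates + 1):
            noise = rng.lognormal(0.0, config.sigma, size=n_probes) if config.sigma else 1.0
            data[f"{code}_rep{r}"] = config.background_level * mean_fold * noise
    for r in range(1, config.background_replicates + 1):
        noise = rng.lognormal(0.0, config.sigma, size=n_probes) if config.sigma else 1.0
        data[f"BG_rep{r}"] = config.background_level * np.ones(n_probes) * noise

    df = pd.DataFrame(data, index=pd.Index(probe_ids, name="probe_id"))
    df.insert(0, "probe_class", probe_class)
    df.insert(
        1, "gene_id",
        pd.Series(gene_ids + [pd.NA] * (n_probes - n_genes), index=df.index, dtype="string"),
    )
    for j, code in enumerate(codes):
        df[f"true_occ_{code}"] = true_occ[:, j]
    df["true_pattern"] = ["(" + p + ")" for p in rows_pattern] + [""] * (n_probes - n_genes)
    return df


def generate_group_medians(
    config: SyntheticConfig | None = None,
    n_factors: int | None = None,
    patterns: Sequence[Sequence[str]] | None = None,
) -> tuple[FactorOrder, pd.DataFrame]:
    """Archetype group-median table: one row per H/L pattern.

    With the canonical archetypes (L = 5%, H = 40%) this is the direct
    modeling input for the 2^n-group compatibility charts.  Returns the
    association order and a valid occupancy table (group-name index).
    """
    if config is None:
        config = SyntheticConfig(n_factors=n_factors if n_factors is not None else 3)
    codes = config.resolved_codes()
    if patterns is None:
        patterns = archetype_patterns(config.n_factors)
    rows = {}
    for pattern in patterns:
        pattern = tuple(pattern)
        if len(pattern) != len(codes):
            raise ValueError(f"pattern {pattern} does not match {len(codes)} factors")
        name = "(" + ",".join(pattern) + ")"
        rows[name] = [float(config.archetypes[letter]) for letter in pattern]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(codes))
    table.index.name = "group"
    return FactorOrder(codes), table
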