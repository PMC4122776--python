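"""Ready-made synthetic fixture configurations.

``oracle_config`` is a small (30 kb) landscape with one pair of
~90%-identical sibling subfamilies, sized so the brute-force oracle is
fast; ``benchmark_config`` is a 500 kb landscape with LINE-like and
SINE-like homology groups plus independent subfamilies, used for the
counting-strategy benchmark with enrichment planted on the LINE-like
group.
"""

from __future__ import annotations

from .fixtures import FixtureConfig, SubfamilySpec


def oracle_config(seed: int = 0) -> FixtureConfig:
    return FixtureConfig(
        contigs={"chrT": 30_000},
        subfamilies=[
            SubfamilySpec("RepA", "L1X", "LINE", 400, 5,
                          copy_divergence=0.01, homology_group="L1X",
                          group_divergence=0.05),
            SubfamilySpec("RepB", "L1X", "LINE", 400, 5,
                          copy_divergence=0.01, homology_group="L1X",
                          group_divergence=0.05),
            SubfamilySpec("RepC", "TigX", "DNA", 300, 4, copy_divergence=0.02),
        ],
        seed=seed,
    )


def benchmark_config(seed: int = 0) -> FixtureConfig:
    return FixtureConfig(
        contigs={"chrS": 500_000},
        subfamilies=[
            # copy numbers differ within each homology group so that
            # within-class abundance has real spread (per-class R^2 is
            # otherwise degenerate)
            SubfamilySpec("L1Xa", "L1X", "LINE", 1500, 20,
                          copy_divergence=0.01, homology_group="L1X",
                          group_divergence=0.05),
            SubfamilySpec("L1Xb", "L1X", "LINE", 1500, 14,
                          copy_divergence=0.01, homology_group="L1X",
                          group_divergence=0.05),
            SubfamilySpec("L1Xc", "L1X", "LINE", 1500, 8,
                          copy_divergence=0.01, homology_group="L1X",
                          group_divergence=0.05),
            SubfamilySpec("AluXa", "AluX", "SINE", 300, 40,
                          copy_divergence=0.01, homology_group="AluX",
                          group_divergence=0.04),
            SubfamilySpec("AluXb", "AluX", "SINE", 300, 20,
                          copy_divergence=0.01, homology_group="AluX",
                          group_divergence=0.04),
            SubfamilySpec("AluXc", "AluX", "SINE", 300, 12,
                          copy_divergence=0.01, homology_group="AluX",
                          group_divergence=0.04),
            SubfamilySpec("TigX", "TigX", "DNA", 500, 20, copy_divergence=0.03),
            SubfamilySpec("TigY", "TigY", "DNA", 600, 15, copy_divergence=0.03),
            SubfamilySpec("ERVX", "ERVX", "LTR", 800, 10, copy_divergence=0.02),
        ],
        seed=seed,
    )


ENRICHED_CLASS = "LINE"  # the planted-enrichment homology group's class


def enriched_feature_intervals(toy) -> list[tuple[int, int]]:
    """Feature intervals (on the single benchmark contig) covering the
    instances of the enriched class."""
    return [
        (inst.start, inst.end)
        for inst in toy.instances
        if inst.repclass == ENRICHED_CLASS
    ]
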