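import numpy as np
import pandas as pd
import pytest

import chromshift as cs
from chromshift.pipeline import PipelineConfig, mark_density_table

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle with planted ground truth (shared)."""
    return cs.simulate_bundle(cs.SimParams(), seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def rpm_table(bundle):
    """Per-gene rpm_max for every mark/MeDIP track of the default bundle."""
    return mark_density_table(bundle.readsets, bundle.annotation,
                              PipelineConfig())


@pytest.fixture(scope="session")
def transition_table(rpm_table):
    return cs.build_transition_table(
        rpm_table[["k4_A", "k4_B", "k27_A", "k27_B"]])


@pytest.fixture(scope="session")
def fold_table(bundle):
    norm = cs.normalize_global(bundle.expression)
    return cs.fold_change(norm, "MEFp2",
                          ["RasV12_d3", "RasV12_d7", "RasV12_d10"])


@pytest.fixture()
def small_readset():
    """Tiny deterministic read set on one chromosome."""
    rows = [("chr1", 100, 136, "+"), ("chr1", 500, 536, "-"),
            ("chr1", 1000, 1036, "+"), ("chr1", 1005, 1041, "+"),
            ("chr2", 700, 736, "+")]
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return cs.MappedReadSet("tiny", reads, total_mapped=1_000_000)


def brute_force_rpm_max(positions: np.ndarray, tss: int, flank: int,
                        window: int, total_mapped: int) -> float:
    """Independent oracle: scan every integer center in [tss-flank, tss+flank]."""
    positions = np.sort(positions)
    best = 0
    for center in range(tss - flank, tss + flank + 1):
        lo = center - window // 2
        n = (np.searchsorted(positions, lo + window, "left")
             - np.searchsorted(positions, lo, "left"))
        best = max(best, int(n))
    return 1e6 * best / total_mapped
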