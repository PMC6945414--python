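import numpy as np
import pytest

from rocpartials import ScoredDataset, SimulationConfig, simulate_scores


@pytest.fixture
def toy() -> ScoredDataset:
    """Four instances whose staircase, measures and matrix are known by hand.

    Descending order: positive 0.9, negative 0.7, positive 0.4, negative 0.2.
    Vertices (0,0),(0,.5),(.5,.5),(.5,1),(1,1); AUC = c = 0.75.
    """
    return ScoredDataset(scores=[0.9, 0.7, 0.4, 0.2], labels=[1, 0, 1, 0])


def random_dataset(seed: int, with_ties: bool | None = None) -> ScoredDataset:
    """Small binormal dataset with P, N in [2, 40]; every other seed quantized."""
    rng = np.random.default_rng(seed)
    P = int(rng.integers(2, 41))
    N = int(rng.integers(2, 41))
    ties = bool(seed % 2) if with_ties is None else with_ties
    config = SimulationConfig(
        P=P,
        N=N,
        mean_separation=float(rng.uniform(0.0, 2.5)),
        tie_quantization=0.5 if ties else None,
        seed=seed,
    )
    return simulate_scores(config)


def random_boundaries(seed: int, q: int | None = None) -> list[float]:
    """Random ascending FPR boundary list 0 < b_1 < ... < 1 with q parts."""
    rng = np.random.default_rng(seed + 10_000)
    q = int(rng.integers(2, 6)) if q is None else q
    inner = np.sort(rng.uniform(0.02, 0.98, size=q - 1))
    # ensure strict ascent after float rounding
    inner = np.unique(np.round(inner, 6))
    return [0.0, *inner.tolist(), 1.0]
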