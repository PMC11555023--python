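import numpy as np
import pytest

from tapjid.jid import JIDGrid, compute_jid, make_pairs
from tapjid.synthetic import DailyCountLaw, SynthConfig, generate_day, generate_study


@pytest.fixture(scope="session")
def default_grid() -> JIDGrid:
    return JIDGrid()


@pytest.fixture(scope="session")
def small_study():
    """A small but structurally complete study: 6/4/5 days, seizure in taper."""
    cfg = SynthConfig(
        n_pre=6,
        n_taper=4,
        n_post=5,
        seizure_day_index=8,
        seed=42,
        daily_count_law=DailyCountLaw(name="lognormal", median=400, sigma=0.3),
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def baseline_day_jids():
    """20 daily JIDs drawn from the baseline condition (null material)."""
    cfg = SynthConfig(
        n_pre=0, n_taper=0, n_post=0, seizure_day_index=None, seed=7,
        daily_count_law=DailyCountLaw(name="lognormal", median=400, sigma=0.3),
    )

    def one(i):
        stream = generate_day(cfg, "baseline", i)
        return compute_jid(make_pairs(np.diff(stream.timestamps) / 1000.0))

    return [one(i) for i in range(20)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 4):
    """Independent connected-component oracle: breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if dr or dc]
    components = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while queue:
                r, c = queue.pop()
                comp.add((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            components.append(frozenset(comp))
    return components
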