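import numpy as np
import pytest

from dscircuit import synthetic as syn


@pytest.fixture(scope="session")
def schedule8x3():
    """Standard 8-direction, 3-trial block-shuffled moving-bar run."""
    return syn.generate_stimulus_schedule(8, 3, 2.96, seed=7)


@pytest.fixture(scope="session")
def directions8():
    return 45.0 * np.arange(8)


def make_population_movie(seed, n_ds=20, n_flat=20, field=128, kappa=4.0,
                          noise_sd=0.05, response_class="ON-OFF"):
    """Jittered-grid population of DS (von Mises κ) and untuned cells."""
    rng = np.random.default_rng(seed)
    sched = syn.generate_stimulus_schedule(8, 3, 2.96, seed=seed)
    n = n_ds + n_flat
    prefs = np.tile([0.0, 90.0, 180.0, 270.0], (n_ds + 3) // 4)[:n_ds]
    centers = []
    cols = int(np.ceil(np.sqrt(n * field / field)))
    pitch = (field - 24) / max(cols - 1, 1)
    for gy in range(cols):
        for gx in range(cols):
            if len(centers) >= n:
                break
            centers.append((12 + gx * pitch + rng.uniform(-2, 2),
                            12 + gy * pitch + rng.uniform(-2, 2)))
    rng.shuffle(centers)
    cells = [syn.CellSpec(centers[i], 4.0, 1.0, kappa, prefs[i],
                          response_class) for i in range(n_ds)]
    cells += [syn.CellSpec(centers[n_ds + i], 4.0, 1.0, 0.0, 0.0,
                           response_class) for i in range(n_flat)]
    movie, manifest = syn.generate_calcium_movie(
        sched, (field, field), cells, noise_sd=noise_sd, seed=seed + 1)
    return movie, sched, manifest


@pytest.fixture(scope="session")
def population_movie():
    return make_population_movie(seed=21)
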