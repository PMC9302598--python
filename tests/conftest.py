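import numpy as np
import pytest

import locusdyn as ld


def brute_force_tamsd(frames, x, y, max_lag):
    """Independent O(N·lag) double-loop TA-MSD oracle with gap handling."""
    frames = list(frames)
    pos = {f: (xi, yi) for f, xi, yi in zip(frames, x, y)}
    lags, msds, counts = [], [], []
    for lag in range(1, max_lag + 1):
        sq = []
        for f in frames:
            if f + lag in pos:
                dx = pos[f + lag][0] - pos[f][0]
                dy = pos[f + lag][1] - pos[f][1]
                sq.append(dx * dx + dy * dy)
        if sq:
            lags.append(lag)
            msds.append(sum(sq) / len(sq))
            counts.append(len(sq))
    return lags, msds, counts


@pytest.fixture(scope="session")
def immobile_calibration():
    """Fixed-cell calibration shared by mixture tests (preset sigma_loc)."""
    params = ld.MotionParams(model="immobile", sigma_loc=0.10, dt=0.1, n_steps=1200)
    tracks = ld.simulate_immobile(params, 600, seed=5)
    table = ld.dapp_table(tracks)
    return ld.calibrate_dfix(ld.DappDistribution(table["d_app"].to_numpy()))


@pytest.fixture(scope="session")
def single_spot_image():
    """One bright rendered spot at a known position, plus its truth."""
    track = ld.Track(0, np.arange(2), [3.25, 3.25], [2.75, 2.75], dt=0.1)
    track.x_true = track.x.copy()
    track.y_true = track.y.copy()
    imaging = ld.ImagingParams(
        pixel_size=0.16, frame_shape=(40, 40), psf_sigma=0.15,
        photons_per_spot=5000, background=10, gaussian_read_noise=1,
    )
    stack = ld.render_movie([track], imaging, seed=3)
    return stack, track
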