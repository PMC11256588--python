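import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_subject():
    """One deterministic noise-free phantom subject shared across tests."""
    from cbss import PhantomSpec, generate_subject

    spec = PhantomSpec(noise_model="none", seed=11)
    return spec, generate_subject(spec, 0)


@pytest.fixture(scope="session")
def noiseless_fitted(noiseless_subject):
    """The noise-free subject taken through mask, parcellation and fit."""
    from cbss import csf_mask, fit_pdiff_map, propagate_labels

    spec, sub = noiseless_subject
    mask = csf_mask(sub.free_water, sub.anat)
    parc = propagate_labels(sub.atlas, mask.mask.data, sub.anat)
    pm = fit_pdiff_map(sub.series, sub.free_water, mask.mask.data)
    return spec, sub, mask, parc, pm


def brute_force_nearest_labels(targets, atlas_labels, spacing):
    """Independent O(N*M) oracle: exhaustive scan over every labelled
    voxel with the canonical squared-distance formula; ties to the
    lowest code."""
    targets = np.asarray(targets)
    sx, sy, sz = spacing
    codes = sorted(set(np.unique(atlas_labels)) - {0})
    best_d = np.full(targets.shape[0], np.inf)
    best_code = np.zeros(targets.shape[0], dtype=np.asarray(atlas_labels).dtype)
    for code in codes:  # ascending: strict '<' keeps the lowest code on ties
        pts = np.argwhere(np.asarray(atlas_labels) == code)
        delta = targets[:, None, :] - pts[None, :, :]
        d2 = ((delta[..., 0] * sx) ** 2 + (delta[..., 1] * sy) ** 2) + (delta[..., 2] * sz) ** 2
        dmin = d2.min(axis=1)
        take = dmin < best_d
        best_d[take] = dmin[take]
        best_code[take] = code
    return best_code
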