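import numpy as np
import pytest

from isoniche.io import IsotopeSample, SpeciesGroup
from isoniche.synthetic import arreo_fixture


@pytest.fixture
def make_group():
    """Factory: SpeciesGroup from an (n, 2) array of (d13C, d15N) points."""

    def _make(points, species="sp", ecosystem="eco", role="consumer",
              provenance="resident"):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return SpeciesGroup(
            species,
            [
                IsotopeSample(
                    species=species, ecosystem=ecosystem, role=role,
                    d13C=float(c), d15N=float(n), provenance=provenance,
                )
                for c, n in pts
            ],
        )

    return _make


@pytest.fixture(scope="session")
def arreo():
    """Deterministic lake-community fixture: (target, donors)."""
    return arreo_fixture(seed=20_000)
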