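import numpy as np
import pytest

from lhlkit import structure_io as sio
from lhlkit import synthetic_data as synth


@pytest.fixture(scope="session")
def scaffold():
    return synth.make_scaffold(4, 5)


def build_structure(coord_sets, structure_id="s", start_index=1, aa="A"):
    """BackboneStructure from a list of atom-name->xyz dicts."""
    residues = [
        sio.Residue(index=start_index + i, aa=aa, coords=dict(c))
        for i, c in enumerate(coord_sets)
    ]
    return sio.BackboneStructure(id=structure_id, residues=residues)


@pytest.fixture(scope="session")
def cohort_factory(scaffold):
    """Generate n clash-free annotated LHL variants in a given regime."""
    sc, sc_ann = scaffold

    def make(n, seed=0, regime="diverse", with_truth=False):
        rng = np.random.default_rng(seed)
        spec_fn = (synth.random_variant_spec if regime == "diverse"
                   else synth.regular_variant_spec)
        out = []
        while len(out) < n:
            spec = spec_fn(rng)
            try:
                s, a, truths = synth.make_lhl_variant(
                    sc, sc_ann, spec, variant_id=f"{regime}{len(out):04d}"
                )
            except sio.StructureError:
                continue
            out.append((s.id, s, a, truths) if with_truth else (s.id, s, a))
        return out

    return make


@pytest.fixture(scope="session")
def small_cohort(cohort_factory):
    return cohort_factory(6, seed=42)
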