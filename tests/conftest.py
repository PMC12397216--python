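import numpy as np
import pytest

import devatlas as da
from devatlas.synthetic import PhantomSpec, make_analytic_field, make_phantom

SHAPE = (32, 32, 32)
ANCHORS = (4, 7, 14, 21, 28, 56)


def centroid(values: np.ndarray) -> np.ndarray:
    grid = np.indices(values.shape, dtype=float)
    mass = values.sum()
    return np.array([(grid[i] * values).sum() / mass for i in range(3)])


@pytest.fixture
def space():
    return da.make_space(28, SHAPE)


@pytest.fixture
def gaussian_blob(space):
    grid = np.indices(SHAPE, dtype=float)
    c = (np.asarray(SHAPE) - 1) / 2.0
    r2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
    return da.IntensityVolume(space=space, values=np.exp(-r2 / (2 * 7.0**2)))


def build_translation_chain(step_offset=(1.0, 1.0, 0.0), shape=SHAPE,
                            anchors=ANCHORS):
    """Chain whose adjacent backward fields are pure translations and whose
    templates are correspondingly shifted copies of the youngest phantom.

    The backward field for (older, younger) is the constant pull field
    ``U = offset``, which shifts content by ``-offset``; templates are
    rolled so that each anchor's template is exactly the previous one
    displaced by ``offset`` per adjacent pair.
    """
    base, _ = make_phantom(PhantomSpec(age=anchors[0], shape=shape,
                                       base_semi_axes=(5.0, 4.0, 4.0),
                                       growth_per_day=(0.05, 0.05, 0.05)))
    offset = np.asarray(step_offset, dtype=float)
    shift_int = offset.astype(int)
    assert np.all(shift_int == offset), "integer offsets keep templates exact"
    templates = {anchors[0]: base}
    fields = {}
    values = base.values
    for younger, older in zip(anchors, anchors[1:]):
        values = np.roll(values, shift_int, axis=(0, 1, 2))
        templates[older] = da.IntensityVolume(
            space=da.make_space(older, shape), values=values)
        fields[(older, younger)] = make_analytic_field(
            "translation", {"offset": offset},
            source=da.make_space(older, shape),
            target=da.make_space(younger, shape))
    return da.TemplateChain(anchor_ages=anchors, backward_fields=fields,
                            templates=templates)


@pytest.fixture
def translation_chain():
    return build_translation_chain()


@pytest.fixture
def zero_chain():
    """Two-anchor chain with an identity backward field and one template."""
    shape = SHAPE
    t, labels = make_phantom(PhantomSpec(age=28, shape=shape))
    s56 = da.make_space(56, shape)
    zero = da.zero_field(source=s56, target=da.make_space(4, shape))
    tmpl = {4: da.IntensityVolume(space=da.make_space(4, shape),
                                  values=t.values),
            56: da.IntensityVolume(space=s56, values=t.values)}
    return da.TemplateChain(anchor_ages=(4, 56),
                            backward_fields={(56, 4): zero},
                            templates=tmpl)
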