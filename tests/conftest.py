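import math

import pytest

from chemscan.drawing import (
    Drawing,
    DrawnAtom,
    DrawnBond,
    DrawnFragment,
    to_cdxml,
)
from chemscan.layout import IdAlloc, make_text
from chemscan.library import load_libraries


@pytest.fixture(scope="session")
def libs():
    return load_libraries()


def ring_drawing(node_kind: str | None = None, node_label: str | None = None,
                 extra_texts: tuple[str, ...] = (), node_bonds: int = 1):
    """Benzene ring, optionally carrying one labelled node (abbreviation or
    R-group) attached by ``node_bonds`` bonds, plus free text blocks."""
    ids = IdAlloc()
    d = Drawing()
    f = DrawnFragment(id=ids())
    rid = []
    for k in range(6):
        a = math.radians(60 * k)
        f.atoms.append(DrawnAtom(id=ids(), x=150 + 30 * math.cos(a),
                                 y=150 + 30 * math.sin(a)))
        rid.append(f.atoms[-1].id)
    for k in range(6):
        f.bonds.append(DrawnBond(id=ids(), begin=rid[k], end=rid[(k + 1) % 6],
                                 order=2 if k % 2 == 0 else 1))
    if node_kind is not None:
        f.atoms.append(DrawnAtom(id=ids(), x=210, y=150, label=node_label,
                                 kind=node_kind))
        for k in range(node_bonds):
            f.bonds.append(DrawnBond(id=ids(), begin=rid[k],
                                     end=f.atoms[-1].id))
    d.fragments.append(f)
    for t in extra_texts:
        d.texts.append(make_text(ids, t, 150, 260))
    return d


@pytest.fixture
def ring_cdxml():
    def build(**kwargs) -> str:
        return to_cdxml(ring_drawing(**kwargs))

    return build
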