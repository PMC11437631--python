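import numpy as np
import pytest

import retmorph as rm


@pytest.fixture(scope="session")
def disc():
    return rm.DiscGeometry((350.0, 350.0), 110.0)


@pytest.fixture(scope="session")
def arcade_pair(disc):
    """One deterministic synthetic image: superior+inferior arcades."""
    sup, inf = rm.generate_arcade_pair(disc, vessel_class="artery", seed=3)
    return sup, inf


@pytest.fixture(scope="session")
def arcade_mask(arcade_pair):
    return rm.render_trees(list(arcade_pair), 700, 700)


@pytest.fixture(scope="session")
def arcade_graph(arcade_mask, disc):
    return rm.extract_graph(arcade_mask, disc)


def brute_force_strahler(children: dict, roots) -> dict:
    """Independent post-order Strahler recursion on an id-keyed tree.

    ``children`` maps a segment/edge id to its daughter ids. Kept
    deliberately separate from the package implementation: iterative
    explicit-stack post-order, order bump when >=2 daughters tie at the
    maximum.
    """
    order = {}
    for root in roots:
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            kids = children.get(node, [])
            if not kids:
                order[node] = 1
                continue
            if not done:
                stack.append((node, True))
                stack.extend((k, False) for k in kids)
            else:
                sub = sorted((order[k] for k in kids), reverse=True)
                m = sub[0]
                order[node] = m + 1 if len(sub) > 1 and sub[1] == m else m
    return order


@pytest.fixture(scope="session")
def strahler_oracle():
    return brute_force_strahler
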