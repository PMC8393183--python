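"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_coreness(net) -> dict:
    """Multiplex coreness oracle: repeatedly delete a minimum-total-degree
    region from all layers, recording the running degree threshold."""
    adj = [a.copy() for a in net.adjacency]
    alive = set(range(net.n_regions))
    core = {}
    k = 0
    while alive:
        degs = {i: sum(a[i].sum() for a in adj) for i in alive}
        v = min(alive, key=lambda i: (degs[i], i))
        k = max(k, int(degs[v]))
        core[net.region_labels[v]] = k
        for a in adj:
            a[v, :] = 0
            a[:, v] = 0
        alive.remove(v)
    return core
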