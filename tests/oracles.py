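"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def brute_force_minimax(total, profiles, step=1):
    """Grid-search minimax partition oracle for <= 3 devices.

    Device finish time is ``a * n + T0`` for ``n > 0`` and 0 for idle devices
    (devices allocated nothing never launch).  Returns (best makespan,
    allocation).
    """
    m = len(profiles)

    def cost(alloc):
        return max(p.a * n + p.T0 if n > 0 else 0.0
                   for p, n in zip(profiles, alloc))

    if m == 1:
        return cost([total]), [total]
    if m == 2:
        best, best_alloc = np.inf, None
        for n1 in range(0, total + 1, step):
            c = cost([n1, total - n1])
            if c < best:
                best, best_alloc = c, [n1, total - n1]
        return best, best_alloc
    if m != 3:
        raise ValueError("oracle supports at most 3 devices")
    best, best_alloc = np.inf, None
    for n1 in range(0, total + 1, step):
        rest = total - n1
        n2 = np.arange(0, rest + 1, step)
        n3 = rest - n2
        t1 = profiles[0].a * n1 + profiles[0].T0 if n1 > 0 else 0.0
        t2 = np.where(n2 > 0, profiles[1].a * n2 + profiles[1].T0, 0.0)
        t3 = np.where(n3 > 0, profiles[2].a * n3 + profiles[2].T0, 0.0)
        c = np.maximum(t1, np.maximum(t2, t3))
        i = int(np.argmin(c))
        if c[i] < best:
            best, best_alloc = float(c[i]), [n1, int(n2[i]), int(n3[i])]
    return best, best_alloc
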