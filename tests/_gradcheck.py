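"""Central finite-difference gradient oracle, independent of backward()."""

import numpy as np

from downpourtext import model as model_mod


def finite_difference_grads(doc, params, config, eps=1e-6):
    """Numeric gradient of the single-document loss w.r.t. every tensor,
    using only forward evaluations (dropout disabled)."""
    from downpourtext.preprocess import PAD_INDEX

    grads = {}
    for key, tensor in params.tensors.items():
        g = np.zeros_like(tensor)
        flat = tensor.ravel()
        gflat = g.ravel()
        # the PAD embedding row is a frozen constant (zero vector), not a free
        # parameter; exclude it from the numeric check
        skip = set()
        if key == "embedding":
            width = tensor.shape[1]
            skip = set(range(PAD_INDEX * width, (PAD_INDEX + 1) * width))
        for i in range(flat.size):
            if i in skip:
                continue
            orig = flat[i]
            flat[i] = orig + eps
            lp = model_mod.loss(model_mod.forward(doc, params, config).probs, doc.label_index)
            flat[i] = orig - eps
            lm = model_mod.loss(model_mod.forward(doc, params, config).probs, doc.label_index)
            flat[i] = orig
            gflat[i] = (lp - lm) / (2 * eps)
        grads[key] = g
    return grads


def max_relative_error(analytic, numeric, floor=1e-8):
    """Worst-case elementwise relative error between two gradient dicts."""
    worst = 0.0
    for key in analytic:
        a, n = analytic[key], numeric[key]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), floor)
        err = np.abs(a - n) / denom
        # ignore entries where both gradients are essentially zero
        err[(np.abs(a) < floor) & (np.abs(n) < floor)] = 0.0
        worst = max(worst, float(err.max()))
    return worst
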