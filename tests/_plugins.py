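"""Plugin test targets for the method registry's plugin dispatch."""

import numpy as np

from dabench.core import DAResult


def constant_result(exp, norm):
    m = exp.table.n_features
    return DAResult.from_raw("constant", exp.table.feature_ids,
                             np.full(m, 0.5), np.zeros(m), np.zeros(m, dtype=int))


def boom(exp, norm):
    raise RuntimeError("this method always fails")
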