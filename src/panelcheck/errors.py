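"""Exception types shared across the package."""


class EstimationError(RuntimeError):
    """An estimator could not be computed from the data provided.

    Raised e.g. when no gene has all-positive counts for median-of-ratios
    size factors, or when a variance component has no replication to
    estimate it from. The message names the quantity that failed.
    """
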