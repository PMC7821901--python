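"""Exception types shared across the pipeline.

``InputError`` maps to CLI exit code 2 (malformed or missing inputs),
``DegenerateAnalysisError`` to exit code 3 (analysis not computable on the
given data, e.g. single-class decoding).
"""


class InputError(ValueError):
    """Malformed, missing, or out-of-range input data."""


class DegenerateAnalysisError(RuntimeError):
    """The requested analysis is undefined on the given data."""
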