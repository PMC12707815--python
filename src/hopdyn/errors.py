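"""Exception types shared across the pipeline.

Every hard failure raises :class:`PipelineError` carrying a short machine
readable ``code`` (e.g. ``"missing_marker"``) plus a human readable message.
Soft issues are emitted as :class:`PipelineWarning` via ``warnings.warn``.
"""

from __future__ import annotations


class PipelineError(ValueError):
    """Validation or processing failure with a stable string code."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


class PipelineWarning(UserWarning):
    """Non-fatal data-quality issue (soft segment, clamped angle, ...)."""
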