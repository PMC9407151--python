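"""Exception hierarchy and process exit codes.

Each pipeline stage fails with a distinct exception class so the CLI can
map failures to distinct exit codes (I/O vs configuration vs annotation vs
training vs evaluation).
"""

from __future__ import annotations


class FRFSegError(Exception):
    """Base class for all frfseg errors."""

    exit_code = 1


class ConfigurationError(FRFSegError):
    """Invalid configuration or parameter value."""

    exit_code = 2


class ImageIOError(FRFSegError):
    """Unreadable, undecodable or unserializable raster data."""

    exit_code = 3


class FormatError(ImageIOError):
    """Decodable file with an unsupported layout (e.g. channel count)."""

    exit_code = 3


class AnnotationError(FRFSegError):
    """Label mask / class table inconsistent with each other or the image."""

    exit_code = 4


class TrainingError(FRFSegError):
    """Classifier training preconditions violated."""

    exit_code = 5


class EvaluationError(FRFSegError):
    """Performance evaluation impossible (e.g. one-sided truth)."""

    exit_code = 6


class SamplingError(FRFSegError):
    """Synthetic label sampling request cannot be satisfied."""

    exit_code = 5
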