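"""Exception hierarchy.

Everything raised on purpose derives from :class:`VoxelPipeError` so callers
(and the CLI drivers) can distinguish expected failures from bugs.
"""


class VoxelPipeError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedPixelKindError(VoxelPipeError, TypeError):
    """An operation has no handler for the image's pixel kind."""


class PixelRangeError(VoxelPipeError, ValueError):
    """A pixel value cannot be represented in the requested pixel kind."""


class MissingPoolEntryError(VoxelPipeError, KeyError):
    """Lookup of an absent key in the virtual storage pool."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class DescriptorParseError(VoxelPipeError, ValueError):
    """A filter-descriptor string does not match the grammar.

    ``offset`` is the 0-based character position where parsing failed.
    """

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnknownPluginError(VoxelPipeError, KeyError):
    """A descriptor names a plugin that is not registered."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class ParameterError(VoxelPipeError, ValueError):
    """A plugin parameter is missing, unknown, of the wrong type or out of range."""


class ChainExecutionError(VoxelPipeError, RuntimeError):
    """A pipeline step failed; carries the step index and descriptor text."""

    def __init__(self, step: int, descriptor: str, cause: BaseException):
        super().__init__(f"step {step} ({descriptor!r}): {cause}")
        self.step = step
        self.descriptor = descriptor


class FifoProtocolError(VoxelPipeError, RuntimeError):
    """Push/finalize protocol violation on a streaming filter."""


class StageError(VoxelPipeError, RuntimeError):
    """A named stage of a packaged pipeline failed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


class DegenerateInputError(VoxelPipeError, ValueError):
    """Input does not carry enough structure for the requested model."""


class FormatError(VoxelPipeError, IOError):
    """An image file cannot be read or written in the requested format."""
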