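"""Exception hierarchy for perfmoco."""


class PerfmocoError(Exception):
    """Base class for all perfmoco errors."""


class FormatError(PerfmocoError):
    """A series on disk violates the expected file format."""


class SegmentationParseError(PerfmocoError):
    """A segmentation XML file violates the schema dialect.

    Carries the path of the offending element when available.
    """

    def __init__(self, message, element_path=None):
        if element_path is not None:
            message = f"{message} (at {element_path})"
        super().__init__(message)
        self.element_path = element_path


class PipelineError(PerfmocoError):
    """A motion-compensation pipeline could not proceed."""


class SubsetSelectionError(PipelineError):
    """Quasi-periodic subset selection degenerated below a usable size."""
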