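"""Shared result container for the motion-compensation pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

from .series_model import PerfusionSeries
from .transforms import TransformField


@dataclass
class MocoResult:
    """Outcome of one motion-compensation run.

    ``transforms`` map registered-frame coordinates to original-frame
    coordinates (pull-back), one per frame of the PD-stripped series. A
    failed run carries ``failed=True`` with a reason instead of outputs.
    """

    registered_series: PerfusionSeries | None
    transforms: list[TransformField] | None
    log: list[dict] = field(default_factory=list)
    labels: object = None
    roi: object = None
    passes_used: int = 0
    method: str = ""
    failed: bool = False
    failure_reason: str = ""
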