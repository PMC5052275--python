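"""Model configuration shared by the closed form, the simulator, and inference."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

#: Reference-rate regime rules for trials where the reference stimulus appears
#: before the cue (SOA > COA).  "piecewise": the reference races at the neutral
#: rate until cue onset and at v_r afterwards (memoryless switch).  "fixed": the
#: reference keeps a single rate for its whole race -- the neutral rate when it
#: precedes the cue, v_r otherwise.
REGIME_RULES = ("piecewise", "fixed")


@dataclass(frozen=True)
class ModelConfig:
    """Scalar configuration of the race model.

    Parameters
    ----------
    t0_ms:
        Encoding threshold in milliseconds, applied as a common onset delay to
        every racer (each stimulus must be visible for ``t0`` before its
        exponential race starts).  The fitted base model uses 0.
    regime_rule:
        How the reference rate behaves when the reference is shown before the
        cue; see :data:`REGIME_RULES`.
    """

    t0_ms: float = 0.0
    regime_rule: str = "piecewise"

    def __post_init__(self) -> None:
        if not (self.t0_ms >= 0.0 and self.t0_ms < float("inf")):
            raise ValueError(f"t0_ms must be finite and >= 0, got {self.t0_ms}")
        if self.regime_rule not in REGIME_RULES:
            raise ValueError(
                f"regime_rule must be one of {REGIME_RULES}, got {self.regime_rule!r}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


DEFAULT_CONFIG = ModelConfig()
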