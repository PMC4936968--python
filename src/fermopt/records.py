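"""Run records: one fermentation experiment's settings and responses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["Response", "RunRecord"]

#: Sanity bound: grams of xylitol per gram of xylose consumed cannot
#: greatly exceed 1 (the bioconversion is at most near-stoichiometric).
MAX_YIELD = 1.2


@dataclass(frozen=True)
class Response:
    """Measured response: replicate mean and standard deviation."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("response mean must be non-negative")
        if self.sd < 0:
            raise ValueError("response sd must be non-negative")


@dataclass(frozen=True)
class RunRecord:
    """One experiment: factor settings plus measured responses.

    ``settings`` maps factor name to its physical value; ``responses`` maps
    response name (productivity g/L/h, concentration g/L, yield g/g) to a
    :class:`Response`.  ``flags`` carries bookkeeping such as zero-truncation
    markers from the synthetic generator.
    """

    run_id: int
    settings: Mapping[str, float]
    responses: Mapping[str, Response] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "settings", dict(self.settings))
        resp = {
            k: (v if isinstance(v, Response) else Response(*v))
            for k, v in self.responses.items()
        }
        object.__setattr__(self, "responses", resp)
        y = resp.get("yield")
        if y is not None and y.mean > MAX_YIELD:
            raise ValueError(
                f"run {self.run_id}: yield {y.mean} g/g exceeds the sanity bound {MAX_YIELD}"
            )

    def response_value(self, name: str) -> float:
        try:
            return self.responses[name].mean
        except KeyError:
            raise KeyError(
                f"run {self.run_id} carries no response named {name!r}"
            ) from None
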