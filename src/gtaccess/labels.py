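"""Label vocabularies: the four review categories and their binary consolidation.

The positive binary class means "access to germline genetic testing was
identified" (testing done, recommended, or a counseling referral made).
``No``, ``NotApplicable`` and ``NotSure`` all consolidate to negative.
"""

from __future__ import annotations

import enum


class AccessLabel(str, enum.Enum):
    """Four-category chart-review decision."""

    YES = "Yes"
    NO = "No"
    NOT_APPLICABLE = "NotApplicable"
    NOT_SURE = "NotSure"

    @classmethod
    def parse(cls, value: "str | AccessLabel") -> "AccessLabel":
        if isinstance(value, AccessLabel):
            return value
        key = value.strip().casefold().replace(" ", "").replace("_", "").replace("/", "")
        table = {
            "yes": cls.YES,
            "no": cls.NO,
            "notapplicable": cls.NOT_APPLICABLE,
            "na": cls.NOT_APPLICABLE,
            "notsure": cls.NOT_SURE,
            "unsure": cls.NOT_SURE,
        }
        try:
            return table[key]
        except KeyError:
            raise ValueError(f"not a recognised access label: {value!r}") from None


class BinaryLabel(str, enum.Enum):
    """Binary consolidation of :class:`AccessLabel`."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


def consolidate_to_binary(label: AccessLabel) -> BinaryLabel:
    """Map a four-category label to the binary outcome.

    ``Yes`` is the only positive category; ``No``, ``NotApplicable`` and
    ``NotSure`` are all negative.
    """
    label = AccessLabel.parse(label)
    return BinaryLabel.POSITIVE if label is AccessLabel.YES else BinaryLabel.NEGATIVE
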