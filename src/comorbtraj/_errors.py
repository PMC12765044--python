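"""Exception hierarchy shared across the package."""


class ComorbTrajError(Exception):
    """Base class for package errors."""


class ConfigurationError(ComorbTrajError, ValueError):
    """Invalid generator or analysis configuration (e.g. quartile anchors out of order)."""


class InputError(ComorbTrajError, ValueError):
    """Malformed input data (unparseable dates, invalid months, ...)."""


class OrphanParticipantError(InputError):
    """Event stream references participant ids absent from the participant table."""

    def __init__(self, orphan_ids):
        self.orphan_ids = sorted(map(str, orphan_ids))
        shown = ", ".join(self.orphan_ids[:10])
        more = "" if len(self.orphan_ids) <= 10 else f" (+{len(self.orphan_ids) - 10} more)"
        super().__init__(f"events reference unknown participant ids: {shown}{more}")
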