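"""Exception hierarchy for pipeline stages."""


class ErgoloadError(Exception):
    """Base class for all package errors."""


class FormatError(ErgoloadError):
    """Malformed on-disk signal file or sidecar."""


class SyncError(ErgoloadError):
    """Cross-stream synchronization could not be established."""


class CalibrationError(ErgoloadError):
    """Missing or unusable calibration data (MVC, reference lift, N-pose)."""


class ScenarioError(ErgoloadError):
    """Invalid synthetic-data scenario."""


class ConfigurationError(ErgoloadError):
    """Invalid processing parameters."""


class DesignError(ErgoloadError):
    """Trial dataset does not support the requested analysis."""
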