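"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: input problems exit 2, capability limits
exit 3, and verification mismatches exit 4.
"""


class OrbiteqError(Exception):
    """Base class for all package errors."""


class InputError(OrbiteqError, ValueError):
    """Invalid user input: malformed graphs, out-of-range vertices, bad flags."""


class CapabilityError(OrbiteqError):
    """Request exceeds the documented working range of the tool."""


class ConsistencyError(OrbiteqError, RuntimeError):
    """Internal invariant violated; signals a bug, never swallowed."""


class VerificationError(OrbiteqError):
    """Equation-solved counts disagree with the brute-force oracle."""
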