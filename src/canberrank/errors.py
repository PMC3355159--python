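"""Exception hierarchy shared by the whole package.

Two failure modes are distinguished because they map to different CLI exit
codes: malformed input (exit 2) versus a computation the library refuses to
attempt because it exceeds a declared capability bound (exit 3).
"""


class CanberrankError(Exception):
    """Base class for all package-specific errors."""


class InputError(CanberrankError, ValueError):
    """Invalid user input: bad sizes, duplicate features, unknown tokens."""


class CapabilityError(CanberrankError, RuntimeError):
    """A requested computation exceeds an explicit size bound.

    Raised e.g. when a brute-force enumeration would need more completion
    pairs than the caller's cap, or when an exhaustive search over l!
    orderings is requested beyond the supported list length.
    """
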