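"""Exception hierarchy for the navigation pipeline."""


class NavlabError(Exception):
    """Base class for all package errors."""


class FrameMismatchError(NavlabError):
    """Two transforms were composed whose inner coordinate frames differ."""

    def __init__(self, inner_of_a: str, inner_of_b: str) -> None:
        super().__init__(
            f"cannot compose: left transform starts at frame {inner_of_a!r} "
            f"but right transform ends at frame {inner_of_b!r}"
        )
        self.inner_of_a = inner_of_a
        self.inner_of_b = inner_of_b


class BehindCameraError(NavlabError):
    """A 3D point with non-positive camera-frame depth was projected."""


class DegenerateGeometryError(NavlabError):
    """Point configuration does not constrain a rigid transform (collinear or too few)."""


class InsufficientPosesError(NavlabError):
    """Fewer pose pairs than the hand-eye solver requires."""


class DegenerateMotionError(NavlabError):
    """Pose set lacks the rotational diversity needed for a trustworthy hand-eye solve."""


class VisibilityError(NavlabError):
    """Camera trajectory could not keep all marks inside the image."""
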