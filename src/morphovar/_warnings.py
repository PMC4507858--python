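"""Warning categories used across the package."""


class MorphovarWarning(UserWarning):
    """Base class for all package warnings."""


class OrientationUndefinedWarning(MorphovarWarning):
    """Outline is too close to a circle for the first-harmonic ellipse to
    define a rotation/starting-point normalization."""


class DegenerateReconstructionWarning(MorphovarWarning):
    """Inverse radial reconstruction produced a non-positive radius; the
    descriptor lies outside the method's domain of validity."""


class SmallSampleWarning(MorphovarWarning):
    """Group sample size below the recommended minimum for a stable
    first-eigenvector estimate."""


class AxesClippedWarning(MorphovarWarning):
    """Requested more ordination axes than are available."""


class NegativeEigenvalueWarning(MorphovarWarning):
    """Principal coordinate analysis dropped axes with non-positive
    eigenvalues (non-Euclidean input distances)."""


class ZeroPaddedConfigurationWarning(MorphovarWarning):
    """A configuration with fewer axes was padded with zero columns before
    Procrustes superimposition."""


class UnstableIntervalWarning(MorphovarWarning):
    """Too few bootstrap replicates for a stable percentile bound."""


class ExtraColumnWarning(MorphovarWarning):
    """Input table carried unrecognised columns that were ignored."""
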