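"""Exception hierarchy shared across the package."""


class RyrcnError(Exception):
    """Base class for all package-specific errors."""


class ClusterFormatError(RyrcnError):
    """A cluster file could not be parsed."""


class DuplicateSiteError(ClusterFormatError):
    """Two channels were placed on the same lattice site."""

    def __init__(self, site):
        self.site = site
        super().__init__(f"duplicate lattice site {site!r}: one channel per site")


class EmptyClusterError(RyrcnError):
    """An operation produced or received a cluster with no channels."""


class DisconnectedClusterError(RyrcnError):
    """The analysis requires a single connected cluster.

    The linearized theory relies on Perron-Frobenius structure of the
    adjacency matrix, which only holds for connected lattices. Extract the
    largest component first (``connected_components(cluster)[0]``).
    """
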