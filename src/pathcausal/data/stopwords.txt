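# English stop words removed before term ranking (one per line).
# Tokens shorter than three characters are dropped before this list applies.
about
above
after
again
all
also
and
any
are
because
been
before
being
below
between
both
but
can
cannot
could
did
does
doing
down
during
each
few
for
form
forms
from
further
had
has
have
having
her
here
hers
him
his
how
into
its
itself
may
might
more
most
must
not
now
off
once
one
only
other
our
ours
out
over
own
same
she
should
since
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
thus
too
two
under
until
upon
very
via
was
were
what
when
where
which
while
who
whom
why
will
with
within
without
would
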