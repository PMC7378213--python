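a
about
above
after
again
against
all
also
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
him
his
how
i
if
in
into
is
it
its
itself
just
may
me
might
more
most
must
my
no
nor
not
of
off
on
once
only
or
other
our
ours
out
over
own
per
same
she
should
so
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
to
too
under
until
up
upon
us
very
was
we
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
you
your
yours
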