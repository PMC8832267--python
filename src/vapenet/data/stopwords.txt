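# Default English stop list (surface forms, checked before lemmatization).
a
about
above
across
after
again
against
all
almost
alone
along
already
also
although
always
am
among
an
and
another
any
anybody
anyone
anything
anywhere
are
around
as
at
back
be
became
because
become
becomes
been
before
behind
being
below
beside
besides
between
beyond
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
done
down
during
each
either
else
enough
even
ever
every
everybody
everyone
everything
everywhere
few
for
former
from
front
full
further
get
give
go
had
has
have
having
he
hence
her
here
hers
herself
him
himself
his
how
however
i
if
in
indeed
into
is
it
its
itself
just
keep
last
latter
least
less
many
may
me
meanwhile
might
mine
more
moreover
most
mostly
much
must
my
myself
namely
neither
never
nevertheless
next
no
nobody
none
noone
nor
not
nothing
now
nowhere
of
off
often
on
once
one
only
onto
or
other
others
otherwise
our
ours
ourselves
out
over
own
per
perhaps
please
quite
rather
re
really
regarding
same
say
see
seem
seemed
seeming
seems
serious
several
she
should
since
six
so
some
somebody
somehow
someone
something
sometime
sometimes
somewhere
still
such
take
than
that
the
their
theirs
them
themselves
then
thence
there
thereafter
thereby
therefore
therein
thereupon
these
they
third
this
those
though
three
through
throughout
thru
thus
to
together
too
toward
towards
two
under
unless
until
up
upon
us
used
using
various
very
via
was
we
well
were
what
whatever
when
whence
whenever
where
whereafter
whereas
whereby
wherein
whereupon
wherever
whether
which
while
whither
who
whoever
whole
whom
whose
why
will
with
within
without
would
yet
you
your
yours
yourself
yourselves
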