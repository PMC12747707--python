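# Small English stopword mirror used by tests and worked examples.
a
about
after
also
an
and
are
as
at
be
been
before
but
by
during
for
had
has
have
he
her
here
his
i
if
in
into
is
it
me
my
never
no
not
of
on
or
out
she
so
than
that
the
their
them
then
there
these
they
this
those
to
up
very
was
we
were
when
while
with
without
you
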