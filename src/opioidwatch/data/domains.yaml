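# Site-domain registry for origin classification.
# social_media: identity-linked, short-form networking sites.
# blogs_forums: pseudonymous, topic-focused, long-form sites.
# other: sources outside the surveillance frame (excluded as bad_source).
version: 1
default_class: social_media
domains:
  twitter.com: social_media
  facebook.com: social_media
  myspace.com: social_media
  instagram.com: social_media
  tumblr.com: social_media
  reddit.com: blogs_forums
  blogger.com: blogs_forums
  wordpress.com: blogs_forums
  drugs-forum.com: blogs_forums
  medhelp.org: blogs_forums
  pastebin.com: other
  craigslist.org: other
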