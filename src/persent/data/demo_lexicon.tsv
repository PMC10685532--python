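term	strength
خوب	3
راضی	3
خوشحال	4
صمیمی	3
مهربان	4
عالی	5
تمیز	2
مرتب	2
سریع	2
دلسوز	4
محترم	3
خوشمزه	3
مفید	2
امید	2
راحت	2
شاد	3
قوی	2
دقیق	2
منظم	2
امن	2
خندان	3
گرم	1
خوشایند	3
مودب	2
مناسب	2
بد	-3
کثیف	-2
شلوغ	-3
گران	-2
ناراحت	-3
عصبانی	-3
نگران	-2
ضعیف	-2
کند	-1
سرد	-1
خراب	-3
افتضاح	-5
ناامید	-4
دیر	-1
تلخ	-2
ترسناک	-4
سخت	-2
طولانی	-1
دردناک	-3
غمگین	-3
بی‌نظم	-2
وحشتناک	-5
ضایع	-3
نامناسب	-2
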