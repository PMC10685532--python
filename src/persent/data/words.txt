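بیمار
پرستار
بخش
تخت
دارو
درمان
بیمارستان
اتاق
غذا
ملاقات
نوبت
پذیرش
آزمایش
جراحی
عمل
داروخانه
راهرو
پنجره
ملافه
بالش
صبحانه
ناهار
شام
پرسنل
کارکنان
همراه
خانواده
مادر
پدر
فرزند
هزینه
بیمه
پرداخت
تلفن
تلویزیون
حمام
نظافت
پرونده
پزشک
جواب
نتیجه
سونوگرافی
رادیولوژی
شیمی‌درمانی
سرطان
تومور
متاستاز
عمر
زندگی
کرونا
واکسن
ویزیت
منشی
صندوق
آسانسور
پارکینگ
ورودی
سالن
صندلی
دفترچه
نسخه
قرص
آمپول
سرم
تزریق
خون
فشار
تب
درد
لباس
کفش
ساعت
روز
شب
هفته
ماه
سال
اورژانس
بستری
ترخیص
مرخصی
پرستاری
مراقبت
معاینه
کلینیک
درمانگاه
ازدحام
صف
انتظار
هوا
پنکه
کولر
شوفاژ
پتو
برگه
کارت
همسر
برادر
خواهر
عیادت
گل
کتاب
موبایل
شارژ
پریز
یخچال
میوه
چای
سوپ
برنج
خورشت
نان
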